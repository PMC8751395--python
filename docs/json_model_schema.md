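# JSON model dialect

A one-to-one mirror of the SBML+FBC content, for fast fixtures and
diff-friendly storage. One JSON object per file:

```json
{
 "schema_version": 1,
 "id": "model-id",
 "metabolites": [
  {"id": "glc__D_e", "name": "D-glucose", "compartment": "e0",
   "formula": "C6H12O6", "charge": 0}
 ],
 "reactions": [
  {"id": "EX_glc__D_e", "name": "glucose exchange",
   "stoichiometry": {"glc__D_e": -1.0},
   "lower_bound": -1000.0, "upper_bound": 1000.0,
   "gpr": "", "kind": "exchange"}
 ],
 "genes": ["RL0001"],
 "objective": {"BIOMASS": 1.0},
 "notes": {}
}
```

Field notes:

- `compartment` is a free string; the `[c0]`/`[e0]` cytosol/extracellular
  convention is used by the fixtures but not enforced.
- `formula` and `charge` are optional (`null` when unknown).
- `stoichiometry` maps metabolite id → coefficient; negative = consumed.
  Exchange/sink/demand reactions reference exactly one metabolite, with
  negative flux meaning uptake into the system.
- `gpr` is a boolean expression over gene ids with case-insensitive
  `and`/`or` and parentheses; empty string = no gene requirement. Every
  gene referenced must appear in `genes`.
- `kind` is one of `metabolic`, `transport`, `exchange`, `sink`, `demand`,
  `objective-support`. On SBML round-trips the kind is carried as an SBO
  term and recovered structurally for files written by other tools.
- `objective` maps reaction ids to weights of the linear objective `c`.

Missing bounds default to ±1000 flux units (mmol h⁻¹ gDW⁻¹ by
convention).
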