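# tmdscreen

Quantitative analysis toolkit for split-β-lactamase transmembrane-helix
interaction screens. It covers the full desk workflow around such a screen:

- **`tmdscreen.dose_response`** — fits a decreasing Hill curve
  `y(x) = c / (1 + (x/k)^g)` to ampicillin dose-response plates
  (`k` is the LD50), aggregates replicate fits to mean ± SEM, normalizes
  LD50s to a reference construct, sorts pairs into high (>80%),
  medium (50–80%) and low (<50%) affinity classes, and normalizes GFP
  expression readings to cell density.
- **`tmdscreen.library_design`** — enumerates the focussed combinatorial
  library: a 19-residue poly-Leu/GxxxG template carrying one of {D, E, K, R}
  at one of eight randomized positions (32 variants + backbone = 33 per
  plasmid; 33 × 33 = 1089 ordered pairs), plus TMD orientation shifts and
  hybrid-protein sequence assembly.
- **`tmdscreen.pattern_stats`** — classifies isolated pairs by charge
  relationship (opposite / like / single / none), positional distributions
  and residue spacing, and computes overrepresentation of a sequence
  pattern among isolates against its exhaustively enumerated library prior
  (e.g. the opposite-charge 6/7 pattern: 16/1089 = 0.0147 prior,
  0.0147 × 71 = 1.04 expected).
- **`tmdscreen.screen_sim`** — synthetic-data generator: noisy sigmoid
  dose-response plates and a seeded stochastic two-step ampicillin
  selection (agar plate at 5 µg/mL, then liquid at 30 µg/mL) over the
  library, with a configurable ground-truth affinity model used to test
  every analysis stage end to end.
- **`tmdscreen.pipeline` / `tmdscreen.cli`** — plate-table and isolate-table
  I/O, YAML run configs, and the orchestrated
  fit → aggregate → normalize → classify → pattern-stats run with a
  reproducibility manifest.

## CLI

```sh
tmdscreen library enumerate                 # 33-variant manifest (TSV)
tmdscreen library pairs                     # all 1089 ordered pairs
tmdscreen library assemble --parts parts.yaml

tmdscreen simulate curves --seed 1 --ld50 80 --out plates.csv
tmdscreen fit plates.csv                    # per-pair LD50 mean ± SEM

tmdscreen simulate screen --seed 1 --out isolates.tsv
tmdscreen overrep isolates.tsv --positions 6,7 --relation opposite

tmdscreen run-all --config run.yaml         # full analysis + manifest
```

`run.yaml` keys: `plate_table`, `reference_pair_id`, `out_dir`, optional
`isolate_table`, `r_squared_min`, `predicate_positions`,
`predicate_relation`, `n_isolates`, `seed`.

Plate tables are long-format CSV/TSV with columns
`pair_id, replicate, ampicillin_ug_ml, a544` (optional `condition`);
isolate tables are TSV with
`n_position, n_residue, c_position, c_residue, observed_count,
percent_of_reference`.

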