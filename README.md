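# triadyn

Dynamic structural-balance analysis of signed functional networks.

## The problem

Structural balance theory classifies every triangle of a signed network by
the signs of its three edges: the configurations `+++` and `-+-` (sign
product positive) are *balanced* — internally consistent and theorized to be
stable — while `+-+` and `---` are *imbalanced*, tension-laden and expected
to be transient. Applied to functional brain networks, where edges are
signed correlations between regional activity signals, the theory's core
stability assumption can be tested *dynamically*: build a time-resolved
signed network with sliding-window correlations, track every triangle's
configuration over time, and ask whether balanced configurations really
persist longer and couple more strongly than imbalanced ones.

`triadyn` implements that pipeline end to end for anyone working with
multivariate signal matrices (regions × timepoints, e.g. parcellated
resting-state fMRI):

1. **windows** — sliding-window Pearson correlation (default 50 timepoints,
   step 1), both signs preserved, giving a `T × n × n` signed network.
2. **triads** — for each of the C(n,3) triangles and each window, the
   configuration and the triad energy
   `E = −(S_ij · S_ik · S_jk)^(1/3)` (signed cube root; `E ∈ [−1, 1]`,
   negative ⇔ balanced). Maximal same-state runs become *episodes* with a
   **lifetime** (windows) and an **absolute peak energy** (max |E|).
3. **dynamics** — per-state occurrence distributions and the 4×4 directed
   transition matrix; occurrence[s] ≡ Σ lifetimes of s-episodes, exactly.
4. **surrogate** — Fourier phase-randomized null signals (amplitude
   spectrum, hence autocorrelation and variance, preserved; cross-regional
   phase relationships destroyed), 10 realizations averaged by default.
5. **stats** — paired Wilcoxon signed-rank tests across subjects, Cliff's
   delta effect sizes, Benjamini–Hochberg FDR per comparison family.
6. **synthetic** — piecewise-stationary Gaussian AR(1) generator with
   planted signed block covariance, so the whole pipeline is testable with
   known ground truth and no data download.

## Worked example

```python
import triadyn as td

# one synthetic subject: two 6-region blocks, within-block r = 0.3,
# between-block r alternating -0.4 / +0.4 over six 150-timepoint regimes
cov_anti = td.make_block_covariance(12, [6, 6], within_r=0.3, between_r=-0.4)
cov_pos  = td.make_block_covariance(12, [6, 6], within_r=0.3, between_r=0.4)
regimes = [td.RegimeSpec(150, cov_anti if i % 2 == 0 else cov_pos) for i in range(6)]
cfg = td.SyntheticConfig(n_regions=12, regimes=regimes, ar_coefficient=0.3, seed=1000)
ts = td.generate_series(cfg)

dyn = td.sliding_window_connectivity(ts, td.WindowParams(window_length=50, step=1))
summary = td.subject_summary(dyn)
for s in td.STATE_ORDER:
    print(f"{s.symbol}: lifetime={summary.mean_lifetime[s]:.1f} windows, "
          f"peak |E|={summary.mean_abs_peak_energy[s]:.3f}, "
          f"occurrence={summary.occurrence[s]}")

null = td.surrogate_null_summary(ts, td.WindowParams(50, 1),
                                 td.SurrogateSpec(n_realizations=10, seed=2000))
print(f"balance gap (real):      {summary.balance_gap():.1f} windows")
print(f"balance gap (surrogate): {null.balance_gap():.1f} windows")
```

prints

```
+++: lifetime=56.4 windows, peak |E|=0.270, occurrence=98940
+-+: lifetime=5.9 windows, peak |E|=0.111, occurrence=14675
-+-: lifetime=52.3 windows, peak |E|=0.269, occurrence=71500
---: lifetime=6.3 windows, peak |E|=0.134, occurrence=2105
balance gap (real):      48.3 windows
balance gap (surrogate): 1.2 windows
```

The planted structure behaves as balance theory predicts: the balanced
configurations (`+++`, `-+-`) dwell an order of magnitude longer and reach
higher peak energies than the imbalanced ones, and the balanced-minus-
imbalanced lifetime gap collapses from ≈48 windows to ≈1 window once
phase randomization removes the cross-regional coupling. Group-level
inference over a cohort of such subjects runs through
`td.compare_states(...)` and `td.compare_real_vs_surrogate(...)`.

## Command line

Each stage is also a subcommand (`--help` on any of them):

```bash
triadyn simulate     --config sim.yaml --out subject01.tsv
triadyn connectivity --in subject01.tsv --window 50 --step 1 --out dyn.npz
triadyn triads       --in dyn.npz --out-episodes episodes.tsv --out-summary summary.json
triadyn surrogate    --in subject01.tsv --n 10 --seed 7 --window 50 --out null.json
triadyn stats        --summaries s1.json --summaries s2.json ... --out group/
triadyn run          --config pipeline.yaml            # full multi-subject pipeline
```

Signals travel as plain TSV/CSV matrices (one row per region, a
`#tr_seconds=` comment carrying the sampling interval); summaries are JSON
keyed by the state symbols; the full pipeline writes episode tables, group
comparison tables, occurrence/transition matrices and a run manifest with
versions, seed and a config+input hash.

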