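# psmclock

An agent-based model of the zebrafish pre-somitic mesoderm (PSM) and its
segmentation clock, for asking how robust clock dynamics are to changes in
tissue morphogenesis.

During somitogenesis, somites are patterned by a tissue-wide genetic
oscillator (the segmentation clock) whose phase is arrested at the anterior
wavefront of the PSM. The PSM itself is simultaneously being built and
consumed: cells ingress from surrounding tissues, mix, divide, and advect
anteriorly as the tissue elongates and, late in development, compacts.
`psmclock` simulates ~2,300 point-cells confined to a horseshoe-shaped
domain (two lateral cylinders joined by a half-torus tailbud), each carrying
a noisy phase oscillator

    dθ_i/dt = ω(x_i) + (κ/N_i) Σ_{|x_j−x_i|≤d_c} sin(θ_j* − θ_i) + √(2D_θ) ξ_i ,

with a posterior-to-anterior intrinsic frequency gradient ω(x), coupling to
neighbours within one cell diameter (optionally delayed by τ, the delta-notch
signal transduction time), and cell movement driven by advection, a
posterior-biased persistent random walk, soft volume exclusion, and a
boundary confinement force. The phenotype read-outs are the Kuramoto order
parameter r and the mean oscillation frequency of the dc-wide strip of cells
at the left anterior wavefront — the cells about to pattern a somite.

The package is aimed at quantitative developmental biologists and modellers
who want to vary morphogenetic processes — where cells ingress (random / DP /
DP+LV scenarios), how fast they mix, how long and dense the tissue is,
whether cells divide (with clock arrest during M-phase), whether coupling is
delayed, and whether the tissue undergoes compaction–extension — and measure
the clock's response under zebrafish parameters.

## Worked example

```python
from psmclock import preset, run

traj = run(preset("fig2_dp", seed=1, dt=0.02))   # dorso-posterior ingression
end = traj.metrics.iloc[-1]
print(f"t = {end['t']:.0f} min  anterior r = {end['r_anterior']:.3f}  "
      f"mean dθ/dt = {end['mean_freq']:.4f} /min  Δ = {end['delta_freq']:+.4f} /min")
```

```
t = 1000 min  anterior r = 0.968  mean dθ/dt = 0.1359 /min  Δ = -0.0055 /min
```

After 1000 minutes of dorso-posterior ingression the anterior strip is still
tightly synchronized (r = 0.97; r = 1 would be perfect phase alignment), and
its mean frequency sits within ~4% of the intrinsic-gradient average over the
strip (Δ ≈ 0) — the clock is robust to this ingression mode. Replacing the
preset with `"fig8_delay"` (coupling delay τ = 21 min) collapses r to ≈ 0.1:
with the experimentally measured delay, the same tissue fails to stay
synchronized.

The same runs are available from a shell:

```bash
psmclock run --preset fig2_dp --seed 1 --set dt=0.02 --out out/dp
psmclock sweep --grid fig7_coupling_sweep --preset fig2_random --reps 10 --out out/k_vs
```

`run` writes `metrics.csv` (t, anterior r, mean and excess frequency, cell
counts, turnover counters), optional per-cell `snapshots.csv`, and a
`run.json` config echo; `sweep` writes raw per-run and median/IQR summary
tables.

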