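# mmtrack

Joint segmentation/tracking and single-cell quantification for
mother-machine time-lapse microscopy.

Mother machines trap bacteria in dead-end growth channels in single file,
which makes long-term single-cell observation possible but leaves two hard
analysis problems: tracking visually near-identical cells through growth,
division and exit over hundreds of frames, and turning coarse image
measurements into calibrated physical quantities (sizes, growth rates,
absolute protein numbers). `mmtrack` addresses both for people running
mother-machine experiments:

- **Tracking** is formulated as one global integer linear program over an
  excess of candidate cell segments and candidate inter-frame links
  (mapping / division / exit), minimizing total cost
  `C = sum_i v_i c_i` subject to continuity (every cell at an internal
  frame has exactly one past and one future) and conflict constraints
  (at most one active hypothesis per containment path). The ILP is solved
  to *proven* optimality, and manual corrections are just extra linear
  constraints — one edit re-optimizes the channel globally.
- **Growth**: per-cycle rates from linear regression of log-size on time,
  with the posterior error `sigma(a) = sqrt(var(x)(1-r^2)/((T-1)var(t)))`.
- **Fluorescence**: total cell fluorescence from an EM fit of the column-sum
  profile `c_i = noise + B + A/(1 + ((i - i_mid)/w)^2)` (Cauchy peak on a
  background), auto-fluorescence subtraction `A~ = A - alpha S`, and
  bleaching-rate estimation from production-free phases.
- **Absolute calibration**: the fluorescence-per-molecule factor `lambda`
  from binomial partitioning of fluorophores between sibling cells, with a
  likelihood that also accounts for daughter-size fluctuations and
  measurement noise, `var(q_i - rho_i) = v + rho_i(1-rho_i)/(lambda(x_i+y_i))`,
  marginalized over `v` to a posterior on `lambda`.
- **Synthetic data**: a first-class generator of ground-truth lineages and
  rendered image stacks embodying the same generative assumptions, so the
  whole pipeline is testable end to end without external data.

See `docs/methods.md` for the models, assumptions and parameter defaults.

## Worked example

Simulate a 2-hour synthetic channel, track it, and quantify growth:

```python
import numpy as np
from mmtrack.simdata import SimParams, simulate_lineage, render_stack
from mmtrack.pipeline import track_channel, cell_tracks, summarize_growth
from mmtrack.tracking import link_accuracy

params = SimParams(n_frames=120)          # 3-min frames, 0.75 dbl/h, 17% CV
lineage = simulate_lineage(params, seed=5)
stack = render_stack(lineage, seed=6)

result = track_channel(stack.phase)       # hypotheses -> global ILP -> lineage
print(f"link accuracy {link_accuracy(result.cells, lineage):.4f}")

summary = summarize_growth(cell_tracks(result, params.frame_period))
print(f"growth {summary.mean_rate_dbl_h:.3f} dbl/h over {summary.n_cells} "
      f"complete cycles, median r^2 {summary.median_r2_exp:.4f}")
```

prints

```
link accuracy 1.0000
growth 0.759 dbl/h over 15 complete cycles, median r^2 0.9979
```

Every frame-to-frame link matches the generator's ground truth, and the
mean per-cycle growth rate (doublings/hour) lands near the generator's
0.75 dbl/h — the residual gap is the sampling spread of 15 cells drawn with
17% cell-to-cell rate variation. The high median squared correlation of the
log-size fits is the signature of exponential growth.

The same pipeline is available from the shell:

```sh
mmtrack simulate --seed 1 --out sim/
mmtrack track --in sim/channel_phase.tif --fluor sim/channel_fluor.tif --out tracks/
mmtrack quantify --in tracks/ --out growth.csv
mmtrack calibrate --pairs pairs.csv --out lambda.json
```

Curation directives (`mmtrack track --directives edits.json`) are JSON, e.g.
`{"kind": "set_count", "frame": 120, "count": 7}` to fix the number of cells
at a frame, or `force_segment` / `ban_segment` / `force_assignment` /
`ban_assignment` / `clamp` — each becomes one linear constraint and the
channel is re-optimized globally.

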