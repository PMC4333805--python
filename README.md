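# contourfill

A filling-in model of brightness perception in which **collinear/parallel
contour facilitation erases low-contrast boundaries** and thereby triggers
brightness (and darkness) assimilation.

The model has two parallel streams:

- **Feature stream** — ON/OFF *Contrast Pathways* (balanced centre-surround
  receptive fields with divisive/shunting inhibition, silent on uniform
  regions) and ON/OFF *Luminance Pathways* (centre-dominated kernels acting
  as approximate luminance detectors). Their weighted sum feeds the
  filling-in stage.
- **Boundary stream** — *Local Boundary Detection* (polarity-sensitive simple
  nodes pooled into polarity-invariant complex nodes, plus a feedforward
  3×3 MAX for uniform corners), *Global Boundary Detection* (recurrent MAX
  facilitation along contours: long collinear reach, shorter parallel
  reach), and the *L/G Interaction*: the local/global ratio thresholded
  into a binary boundary gate. A weak contour aligned with a strong one is
  facilitated, its ratio collapses, and its boundary is **erased**.

ON and OFF *Filling-in Layers* spread feature activity isotropically by the
same recurrent MAX principle, blocked by the boundary gate and by a relay
threshold that stops spreading over dark (ON) or bright (OFF) surfaces.
Where a gray target's boundary has been erased, the surround's activity
fills it in — assimilation. Brightness is the normalised difference of the
ON and OFF steady states.

All recurrent MAX computations (boundary facilitation and filling-in) run on
one microcircuit (`maxcircuit`): excitatory nodes whose recurrent collaterals
land on distinct dendrites, each gated by dendritic inhibition carrying the
node's own activity, so only stronger-than-self signals pass. Both a
continuous-dynamics solver and the equivalent fixed-point iteration are
provided and are validated against a brute-force component-max oracle.

The package ships a deterministic generator for the sixteen classic displays
simulated with the model (dungeon, cube and grating illusions, square ring
patterns and bullseye, simultaneous brightness contrast, White's effect and
four variants, Benary's cross, Todorović's illusion, checkerboard contrast
in two sizes, contrast-contrast), each bundled with target masks and the
predicted brightness relation, plus an evaluation harness that scores the
model's output against those predictions.

## Command line

```bash
# write one stimulus (PNG + CSV + target masks)
contourfill stimulus --name dungeon --size 128 --out out/

# run the model on one display, writing every intermediate map as a panel
contourfill run --stimulus white --out out/

# the full directional battery (CSV + JSON report, optional panels)
contourfill battery --out out/ [--only sbc,white] [--render]

# a brightness profile along one row, as CSV on stdout
contourfill profile --stimulus sbc --row 64
```

A YAML/JSON config file with sections `pathway`, `bcs` and `fill` can be
passed via `--config` to override any model constant (kernel widths, mixing
weights, facilitation reaches, L/G threshold, filling relay threshold, ...).

## Library sketch

```python
from contourfill import generate_stimulus, run_model
from contourfill.cli_eval import evaluate_case

case = generate_stimulus("dungeon")            # image + masks + prediction
out = run_model(case.image.grid)               # every intermediate map
res = evaluate_case(case, out)                 # scored against the prediction
print(res.target_stats, res.relation_observed, res.passed)
```

Modules: `stimuli` (display generator), `maxcircuit` (dendritic-inhibition
MAX network), `fcs_pathways` (ON/OFF contrast + luminance front end), `bcs`
(local/global boundary detection and the binary gate), `filling_in`
(boundary-gated filling-in, combination, full-model orchestration),
`cli_eval` (evaluation harness and CLI).
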