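# placecell

**Simulation and benchmarking of place-cell classification methods for
1-D calcium-imaging experiments.**

Hippocampal place cells fire when an animal occupies a particular
location, but two-photon calcium imaging gives only a noisy ΔF/F proxy
for firing, and labs use very different statistical criteria to decide
which cells count as place cells.  This package is for experimenters and
methodologists who want to know what those criteria actually select.  It
simulates populations of model CA1 cells on a 200 cm virtual track —
Gaussian place fields with controllable width, peak, reliability and
variability, sampled through realistic locomotion at 7.51 Hz, plus
Poisson shot noise — and runs four published classification methods on
the same ground-truth data:

| method | statistic | criterion |
| --- | --- | --- |
| Peak | max of the fluorescence map | > 99th pct of 500 time-shift shuffles |
| Stability | split-half map correlation *r* | > 95th pct of 100 cross-cell draws |
| Combination | contiguous field + thresholds | field criteria and < 5% of 1000 bootstrap shuffles |
| Information | SI = Σᵢ fᵢ log₂(fᵢ/f̄) | > 95th pct of 500 time-shift shuffles |

Here fᵢ is the mean ΔF/F in location bin *i* of a cell's fluorescence
map (running frames only, speed ≥ 2 cm/s), f̄ the map mean, and the
shuffles displace fluorescence in time relative to position.  Detectors
are scored by sensitivity TP/(TP+FN) and specificity TN/(TN+FP), swept
over model parameters, and compared via the overlap of the populations
they select.  Real locomotion/fluorescence tables can be ingested
through the same pipeline.  See `docs/methods.md` for the model details.

## Worked example

```python
import placecell as pc

lib  = pc.synthesize_traversal_library(184, seed=1)   # traversal pool
loco = pc.assemble_locomotion(lib, 50, seed=2)        # 50-traversal session
fl   = pc.build_population(pc.PopulationSpec(), loco, seed=3)  # 20 place + 80 noise
res  = pc.detect_all(fl.dff, loco.position, loco.velocity,
                     traversal_id=loco.traversal_id, seed=4)
for m, r in res.items():
    cc = pc.confusion(r.labels, fl.truth_labels)
    print(f"{m:12s} detected={r.labels.sum():3d}  "
          f"sens={pc.sensitivity(cc):.2f}  spec={pc.specificity(cc):.2f}")
```

prints

```
peak         detected= 20  sens=1.00  spec=1.00
stability    detected= 24  sens=1.00  spec=0.95
combination  detected= 20  sens=1.00  spec=1.00
information  detected= 24  sens=1.00  spec=0.95
```

i.e. on the default model all four methods find every true place cell
(50 cm fields, peak ΔF/F 1.3, perfectly reliable), while the shuffle
criteria admit false positives at roughly their nominal rates — none of
the 80 noise cells for the Peak method here (top-1% criterion, ~1%
long-run rate) and 4 of 80 for the Information and Stability methods
(top-5% criteria).  Differences between
the methods appear once fields become narrow, weak, unreliable or
variable; `run_sweep` reproduces those regimes:

```python
sw = pc.run_sweep("width", range(20, 201, 20), n_repeats=10, seed=5)
print(sw.summary[["param_width", "method", "sensitivity_mean"]])
```

The same workflow is available from the shell:

```bash
placecell simulate --seed 1 --out session/     # write a synthetic session
placecell detect --seed 1 --out results/       # simulate + classify + score
placecell sweep --parameter width --values 20,50,100,200 --out sweep/
placecell overlap --n-datasets 20 --out overlap/
placecell fixtures --out fixtures/             # tiny example dataset
```

All commands accept `--config config.yaml` (see `placecell.RunConfig`
for every key and its default) and `--seed`; identical seeds give
byte-identical outputs.

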