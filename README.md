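# chromoloop

Equilibrium polymer simulations of chromatin loops and their effect on
enhancer–promoter (E-P) contact frequency.

Distal enhancers regulate promoters through direct spatial contact, and both
are embedded in a network of chromatin loops formed by other regulatory
elements.  `chromoloop` asks a focused physical question: how does a
permanent loop *near* an E-P pair — not involving either of them — change
how often the pair touches?  It models chromatin as a confined semi-flexible
bead–spring ring (one 15 nm monomer per 500 bp, persistence length ~3
monomers, confinement density 0.02 monomers per cubic diameter, soft-core excluded volume that lets fibers
occasionally cross as topoisomerase II would), forms a loop as one extra
harmonic bond, samples the equilibrium ensemble by Langevin dynamics, and
measures the **contact frequency ratio**

    ratio(E, P) = P_loop(contact) / P_no-loop(contact),

the contact frequency of the pair with the loop present divided by the same
quantity in a matched loop-free simulation.  Ratios below 1 mean the loop
*insulates* the pair (enhancer inside the loop, promoter outside); ratios
above 1 mean it *facilitates* them (both loop anchors between enhancer and
promoter).  The package also computes in-silico Hi-C style heatmaps, 4C-like
loop-base profiles, radial chromatin density around the loop, and simulated
FISH distance distributions, so the microscopy and 3C views of the same
physics can be compared.

It is aimed at chromatin biophysicists and computational biologists who want
a self-contained, reproducible implementation of this class of equilibrium
loop models — every published scenario (loop sizes 15/30/60 kb, a 2.5 kb
flexible-fiber loop, densities 1–20%, stiffness variants, topo-II on/off,
phantom chain, two consecutive loops) ships as a named preset with its
matched no-loop control.

## Worked example

Simulate a small scenario — a 2.5 kb loop in a flexible fiber (250
bp/monomer, k = 2, 330-monomer ring) — and score insulation and facilitation
at 5 kb E-P distance (20 monomers):

```python
import dataclasses
import chromoloop as cl
from chromoloop.workbench import get_preset, control_for, simulate_scenario

preset = get_preset("small_flexible_2.5kb")
sched = dataclasses.replace(
    cl.DESK_SCHEDULE, n_blocks=2000, equilibration_blocks=600
)
loop_runs = simulate_scenario(preset.params, sched, seed=7)
ctrl_runs = simulate_scenario(control_for(preset).params, sched, seed=8)

loop_maps = [cl.ensemble_heatmap(e) for e in loop_runs]
ctrl_maps = [cl.ensemble_heatmap(e) for e in ctrl_runs]
loop = preset.params.loops[0]
ins = cl.insulation_score(loop_maps, ctrl_maps, loop, ep_distance=20)
fac = cl.facilitation_score(loop_maps, ctrl_maps, loop, ep_distance=20)
print(f"insulation ratio  {ins.ratio:.2f} +- {ins.stderr:.2f}")
print(f"facilitation ratio {fac.ratio:.2f} +- {fac.stderr:.2f}")
```

which prints (seeds as above):

```
insulation ratio  0.66 +- 0.31
facilitation ratio 5.60 +- 0.55
```

The loop insulates an enhancer inside it from a promoter beyond it (ratio
< 1) and facilitates a pair that straddles it (ratio > 1); the second number
is the spread across the independent looped runs (desk-scale sampling on a
small ring is noisy by design — the numbers above took ~4 minutes on one
core).  The same operations are exposed
on the command line:

```bash
chromoloop presets                          # list all named scenarios
chromoloop simulate --preset one_loop_30kb --schedule desk --seed 1 --out runs/loop
chromoloop simulate --preset one_loop_30kb_control --schedule desk --seed 2 --out runs/ctrl
chromoloop analyze --loop runs/loop/run00.h5 --loop runs/loop/run01.h5 \
    --noloop runs/ctrl/run00.h5 --noloop runs/ctrl/run01.h5 --out report/
chromoloop validate                         # timestep / topology checks
```

`simulate` writes one HDF5 ensemble per run plus per-block diagnostics and a
provenance record; `analyze` writes pooled heatmaps (TSV) and a JSON report
with every window definition echoed.

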