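# juxtacell

Analysis pipeline for contact-dependent, light-based signaling between
synthetic cells (giant unilamellar vesicles, GUVs). It covers the three
quantitative layers of such a system, each testable end-to-end against
synthetic data with known ground truth:

1. **Luminescence kinetics** (`juxtacell.kinetics`) — luciferase decay
   follows `flux(t) = α·K·E·S0·exp(−K·E·t)`; the catalytic rate constant
   `K` is estimated by regressing per-trace log-flux slopes (`λ = K·E`)
   against enzyme concentration, with a 95 % t-interval.
2. **Reaction–diffusion model** (`juxtacell.rdmodel`) — cytosolic SspB
   diffusing in a vesicle cross-section and binding membrane-anchored
   iLID, whose affinity switches between dark (`Kd = 4.7 μM`) and lit
   (`Kd = 132 nM`) states. A conservative finite-volume scheme on the
   radial grid; its steady-state membrane:lumen ratio is checked against
   the closed-form binding equilibrium with depletion,
   `B² − (I+S+Kd)B + IS = 0`, `ratio = B/(S−B)`.
3. **Image quantification** (`juxtacell.imagequant`) — the 30-point
   periphery:lumen ratio of a single vesicle, background-subtracted
   max-normalized line profiles, and the five-line interface ratio
   (3-pixel peak window over the 10 following lumen points, with a plateau
   fallback when no clear peak exists).

`juxtacell.synthdata` generates every input — decay traces, single-vesicle
images (membrane ring, PSF blur, Poisson + read noise), and deflated
vesicle pairs with an enhanced contact interface — from ground-truth
parameters, and `juxtacell.pipeline` orchestrates configured runs and the
Welch t-test group comparison. See `docs/methods.md` for the models,
assumptions, and numerical choices.

## Worked example

Recover a rate constant from synthetic traces and run the
membrane-recruitment model:

```python
import numpy as np
from juxtacell import kinetics, rdmodel, synthdata

# five noiseless decay traces at 1-20 nM enzyme, generated at K = 38207
traces = synthdata.make_trace_set(K=38207.0, E_list=[1e-9, 2e-9, 5e-9, 10e-9, 20e-9])
points = [(t.enzyme_concentration, kinetics.fit_log_slope(t).slope_magnitude)
          for t in traces]
fit = kinetics.estimate_rate_constant(points)
print(f"K_hat = {fit.K_hat:.1f} M^-1 s^-1, CI {fit.ci95}")
# K_hat = 38207.0 M^-1 s^-1, CI (38206.999999999956, 38206.999999999956)

# lit-state steady state inside a 20 um vesicle cross-section
params = rdmodel.RDParams(lit=True)           # 450 nM iLID, 100 nM SspB
res = rdmodel.run_to_steady_state(params)
print(f"membrane:lumen ratio = {res.ratio:.3f}  "
      f"(equilibrium oracle {rdmodel.equilibrium_ratio(params):.3f}), "
      f"mass drift {res.mass_error:.1e}")
# membrane:lumen ratio = 2.848  (equilibrium oracle 2.848), mass drift 6.0e-15
```

The recovered `K_hat` equals the generating constant because noiseless
model traces are exactly log-linear; the lit-state ratio says that at
equilibrium there are ~2.8 SspB molecules on the membrane for every free
one in the lumen, and it matches the closed-form equilibrium because the
conservative discretization shares its steady state.

The same works from the shell:

```sh
juxtacell synth traces --K 38207 --out traces.csv
juxtacell kinetics fit --traces traces.csv --out fit.json
juxtacell rdmodel conditions --config rd.yaml --out conditions.csv
juxtacell synth pair --ratio 2.5 --seed 7 --out pair.tif
juxtacell quant interface --image pair.tif --ann pair.tif.truth.json --out q.csv
juxtacell run --config run.yaml          # full generate -> quantify -> compare
```

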