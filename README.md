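# fibersim

Quantification of the morpho-structural resemblance between two fibrous
extracellular-matrix networks imaged in separate channels — elastin
(two-photon excitation fluorescence) and collagen (second harmonic
generation) — aimed at label-free characterization of skin tissue such
as keloid scars, where aberrant matrix remodeling drives the two fiber
systems toward unusually similar spatial organization.

## What it computes

For a two-channel image pair the package segments fiber masks
$m_E, m_C$ and computes pixel-wise morphology maps per channel: local
coverage (LC, fiber density in a window, $\in[0,1]$), orientation
(axial angle $\theta\in[0,180°)$ from structure-tensor analysis),
directional variance (DV $= 1-R$ with $R$ the doubled-angle mean
resultant length, $\in[0,1]$), waviness (Wav $=1-$ chord/arc over
skeleton segments, $\in[0,1]$), and elastin fiber thickness (medial-axis
width, μm).

The **resemblance metric (RM)** then scores elastin–collagen similarity
per pixel:

1. *Bidirectional nearest-neighbor pairing*: for each elastin fiber
   pixel the nearest collagen pixel (exact Euclidean distance, μm) and
   vice versa — the relation is asymmetric, so both directions are kept.
2. *Difference maps* $MS^F_{Ela}, MS^F_{Col}$: absolute feature
   differences between paired pixels; orientation differences above 90°
   wrap to the complementary angle; a distance pseudo-feature uses the
   pairing distance itself.
3. *Fusion* onto the mask union: each channel's own difference on its
   exclusive pixels, the average on the overlap $m_E \wedge m_C$.
4. *Scoring* to $[0,1]$, decreasing in the fused difference $x$:
   $S_D = [1 + (x/D_{uplim})(e-1)]^{-1}$ with $D_{uplim}$ the maximum of
   the elastin thickness map; $S_L = [1 + x(e-1)]^{-1}$;
   $S_O = \cos x$; and for the collective features (DV, Wav)
   $S = \tfrac12[1-\tanh C(x-\tfrac12)]$ with contrast coefficient
   $C=4$.
5. *Hadamard product*: $RM = S_D S_L S_O S_V S_W \in [0,1]$ on the mask
   union; higher means greater resemblance.

Per sample, the mean and SD of the ten maps (4 features × 2 channels +
elastin thickness + RM) give 20 statistical indicators.  An XGBoost
ranking (split-frequency importance, Bayesian-optimized
hyperparameters), incremental top-n subset selection under repeated
stratified cross-validation, and a k-nearest-neighbor classifier with
leave-one-out validation and one-vs-rest ROC close the loop.

Because no public paired elastin/collagen dataset exists, the package
ships a phantom generator with exact ground truth: random-walk fiber
ribbons with dials for density, orientation concentration, waviness and
thickness, plus a coupling mode in which the collagen channel is a
displaced/rotated copy of the elastin paths — a continuous dial from
identical to unrelated networks.

## Worked example

```python
import numpy as np
from fibersim import PhantomSpec, generate_phantom_pair, compute_rm

# tightly coupled channels: collagen = elastin paths shifted by 1 μm
spec = PhantomSpec(image_size=128, coupling_mode="coupled",
                   coupling_offset=1.0, seed=7)
pair = generate_phantom_pair(spec).pair
stack, maps = compute_rm(pair)
print(f"RM mean {np.nanmean(stack.rm.values):.3f}, "
      f"Duplim {stack.duplim:.2f} um")
```

prints

```
RM mean 0.828, Duplim 7.38 um
```

i.e. the two channels resemble each other strongly (RM near the
identical-channel ceiling of ≈0.964 at C=4; the ceiling is below 1
because the collective-feature sigmoid scores ½(1+tanh 2)≈0.982 even at
zero difference), and the distance score decays on the scale of the
widest elastin fiber (7.38 μm here, where crossing ribbons merge into
wider blobs).  Increasing the coupling offset to 6 μm drops the RM mean
to ≈0.37: the networks no longer track each other.

The CLI mirrors the library:

```bash
fibersim simulate --n-per-class 12 --seed 1 --out run/cohort
fibersim rm --in run/cohort/keloid_000.tif --out run/rm
fibersim stats --cohort run/cohort --out run/stats
fibersim classify --table run/stats/features.csv --k 6 --seed 1 --out run/clf
```

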