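# laminet

Decomposition of time- and frequency-resolved directed cortical connectivity
into concurrent feedforward and feedback networks.

## The problem

Visual stimulation engages several cortical areas at once, over laminar
pathways that carry feedforward (lower → higher areas) and feedback
(higher → lower) influences concurrently, in different frequency bands and
with different time courses.  Given laminar LFP recordings from several
areas, `laminet` estimates the full directed interaction structure and
factorizes it into interpretable processing streams:

1. **tvMVAR** — epochs (trials × channels × time) are fitted with a
   time-varying vector autoregression `x(t) = Σ_k A_k(t) x(t−k) + w(t)`
   using an adaptive Kalman/RLS scheme with forgetting factor *c* = 0.98 and
   order *p* = 15 samples (60 ms at 250 Hz).
2. **iPDC** — the Fourier-transformed coefficients are column-normalized
   into the information partial directed coherence
   `iPDC_ij(f,t) = |Ā_ij| σ_ii^{−1/2} / √(ā_j^H Σw^{−1} ā_j)`,
   a frequency-domain Granger-causal measure insensitive to power
   imbalances, evaluated on a 1–100 Hz × 4-ms grid.
3. **5-way tensor** — per-animal iPDC magnitudes are unfolded to
   source layer × target layer × time × frequency × between-area connection
   (30 directed connections for 6 areas) and averaged over animals.
4. **Nonnegative PARAFAC** —
   `X[sl,tl,t,f,c] ≈ Σ_k a[sl,k]·b[tl,k]·c_t[t,k]·d[f,k]·e[c,k]`,
   fitted by HALS alternating least squares; the component count is selected
   by bootstrap stability and between-component correlation diagnostics.
5. **Characterization** — per network: laminar significance against a
   uniform profile, percent-change dynamics with Bonferroni-corrected
   per-timepoint tests, power-law/lognormal/exponential spectral model
   comparison, rhythmic-modulation spectra, functional hierarchy scores from
   the directed-influence asymmetry index
   `DAI_ij = (e_ij − e_ji)/(e_ij + e_ji)`, receptive-field convergence via
   mixed-effects regression of connection strength on RF-centroid distance,
   and spike–network coupling.

A first-class synthetic-data module (`laminet.synthgen`) generates laminar
LFP epochs from four planted ground-truth networks — a broad scale-free
feedforward web, a gamma-band feedforward network (38/26 Hz at high/low
contrast), and supragranular/infragranular low-frequency feedback networks —
so every stage is verifiable by parameter recovery without any external
data.  See `docs/methods.md` for the model details, the estimation-floor
phenomenology, and what the tests do and do not establish.

## Worked example

```python
import numpy as np
from laminet import synthgen, stok, connectivity, parafac

planted = synthgen.reduced_config("high")          # fast 3-area x 3-layer world
cohort = synthgen.simulate_cohort(planted, n_animals=5, n_trials=150, seed=77)

tensors = []
for ep in cohort:
    model = stok.fit_tvmvar(ep, p=12, c=0.98)      # adaptive tvMVAR
    t = connectivity.ipdc(model, channels=ep.channels, animal=ep.animal)
    tensors.append(np.asarray(connectivity.build_group_tensor([t]).values,
                              np.float32))

K = parafac.select_components(tensors, range(2, 7), n_diag_boots=5,
                              subset_size=4, seed=3, time_stride=2,
                              freq_stride=2, max_iter=150)
print("selected components:", K)
```

prints

```
selected components: 4
```

— the component-number selection recovers the four planted networks.  The
selection diagnostics (available via `return_diagnostics=True`) show why:
at K = 4 every component replicates across animal-subset bootstraps
(intra-bootstrap consistency ≈ 0.88–1.0) while at K = 5 the extra component
fails to replicate (consistency ≈ 0.58), and between-component loading
correlations stay below 0.8.

For an end-to-end run with characterization tables, hierarchy scores, spike
correlations and RF maps written as CSV plus a reproducibility manifest:

```sh
laminet run --config config.yaml --output out/
```

with a minimal `config.yaml`:

```yaml
source: synthetic
seed: 11
params:
  config_scale: reduced
  n_animals: 3
  n_trials: 40
  K: 4
```

## Acceptance script

`scripts/acceptance.py` recomputes the packaged acceptance targets from
scratch by running the pipeline on synthetic data:

* the maximum of the hierarchy module's scaled directed-influence asymmetry
  when a connection has no reciprocal (boundary of the DAI scaling), and
* the number of PARAFAC components selected on a group tensor built from
  the default planted-network configuration (8 simulated animals, 200
  trials each, full tvMVAR → iPDC → unfolding → selection chain).

Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(about 12–15 minutes on one CPU; the JSON maps target ids to recomputed
values).
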