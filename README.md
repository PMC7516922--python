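# afcorr

Dependence measures for paired numeric data, built around the
**Association Factor (AF)** — the distance correlation of optimally
transformed variables — together with the comparator measures it is
benchmarked against (Pearson, distance correlation, MIC, entropic
distance, DFA, detrended Pearson) and a fully synthetic Monte Carlo study
harness. Intended for analysts in biostatistics and epidemiological
modelling who need a single score that detects linear *and* nonlinear
association and degrades gracefully with noise.

## The measure

Pearson's ρ only sees linear structure; the empirical distance correlation

    R²(X,Y) = ν²(X,Y) / sqrt(ν²(X) ν²(Y)),    ν²(X,Y) = (1/n²) Σ_kl A_kl B_kl,

(with A, B the double-centered pairwise-distance matrices) detects any
dependence but its value varies with the *shape* of the relationship:
≈ 0.47 for a noiseless quartic, 0.50 for a parabola, 0.91 for an
exponential, 1.00 for a line. The Association Factor first fits the
optimal transformations h1(X), h2(Y) that linearize the relationship

    h2(Y) = h1(X) + ε,    E[h2] = 0, E[h2²] = 1,

by alternating conditional expectations (h1 ← E[h2|X], h2 ← normalized
E[h1|Y], iterated until the sum of squared errors stops decreasing, with a
rank-space local-linear smoother estimating the conditional expectations)
and then reports

    AF(X,Y) = R(h1(X), h2(Y)).

AF is ≈ 1 for any noiseless functional relationship — and for circular
data, which no function describes — near 0 for independent data, and
empirically symmetric in X and Y. See `docs/methods.md` for the full
model, parameter meanings, and design choices.

## Worked example

Score a two-column CSV (here: 100 points on a noiseless parabola
y = 4(x − 0.5)², x uniform on [0, 1]):

```
$ afcorr compute parab.csv --x x --y y \
      --measures pearson_abs,dcor,af_xy,af_yx,symmetry_gap
measure,value,value_2dp
pearson_abs,0.14798983546,0.15
dcor,0.497345387398,0.5
af_xy,0.999435802698,1.0
af_yx,0.999435805224,1.0
symmetry_gap,2.5265094461e-09,0.0
```

Pearson (0.15) misses the parabola entirely, distance correlation (0.50)
sees it but under-scores it, and AF saturates at 1.0 in both directions
with a negligible directional gap. The same comparison across all four
benchmark relationships:

```
$ afcorr reproduce --tables 1 --out out/
relationship,pearson_abs,dcor,af
linear,1.0,1.0,1.0
poly4,0.0,0.46,1.0
exponential,0.86,0.91,1.0
parabolic,0.0,0.49,1.0
```

From Python:

```python
import numpy as np
from afcorr import PairedSample, association_factor, distance_correlation

x = np.linspace(-1, 1, 100)
s = PairedSample(x, x**4)
association_factor(s).af        # 0.999...
distance_correlation(s).dcor    # 0.457...
```

`afcorr simulate --config suite.json --out DIR --seed S` runs a full
(relationship × noise level) Monte Carlo suite and writes tidy per-trial
and mean CSVs; the JSON schema is documented in `afcorr.io.load_suite_config`.

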