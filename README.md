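# occam

Geometric Bayesian model selection and simplicity preferences in
two-alternative perceptual decisions.

## The problem

A decision-maker sees a cloud of N noisy 2D points and must say which of two
displayed shapes contains the center of the Gaussian that generated them.
Each shape is a *model manifold*: a 0- or 1-parameter family of Gaussian
centers (a point, a segment, or a circular arc). Under equal model priors
the normative answer compares marginal likelihoods

    p(X | M) = ∫ dϑ w(ϑ) p(X | M, ϑ),

with w(ϑ) the Jeffreys prior, and the marginalization over latent causes is
what produces Occam's razor: flexible shapes are penalized because most of
their configurations fit the data poorly. The package implements this
comparison exactly (1D quadrature / closed forms) and through the Fisher
Information Approximation (FIA), a large-N expansion of the log evidence:

    log p(X|M) ≈ log p(X|ϑ̂)
                 − (d/2) log(N/2π)                    (dimensionality)
                 + (N/2)‖l̂‖²_{h⁻¹} + log ΔΦ           (boundary)
                 − log ∫ √g dϑ                        (volume)
                 − ½ log( h(ϑ̂) / g(ϑ̂) )              (robustness)

where ϑ̂ is the maximum-likelihood point, g and h are the expected and
observed per-datum Fisher information, l̂ is the likelihood gradient at ϑ̂,
and ΔΦ is the Gaussian mass the Laplace approximation leaves inside the
parameter domain — a term that engages continuously as ϑ̂ reaches the
domain boundary (it equals −log 2 exactly at the crossing). Each term is a
distinct geometric property of the model, which lets choice behavior be
decomposed into sensitivities to dimensionality, boundary, volume, and
curvature.

On top of the evidence core the package provides:

* **taskgen** — four task variants that each isolate one FIA term
  (point-vs-segment, offset congruent segments, short-vs-long segment,
  straight-vs-curved of equal length), with a calibration routine that tunes
  the observation noise until ideal Bayesian observers beat
  maximum-likelihood observers by ~1 percentage point of accuracy.
* **observers** — simulated decision-makers: maximum-likelihood, FIA,
  exact-Bayes, posterior-sampling, and the Noise-Integration-Noise family
  (sensory noise → partial integration over latent causes → choice
  noise/lapse), plus decision-boundary and k-NN choice maps.
* **sensitivity** — hierarchical Bayesian logistic regression of choices on
  the evidence-term differences, giving population- and participant-level
  *relative sensitivities* (a complexity coefficient divided by the
  likelihood coefficient: 0 = maximum-likelihood behavior, 1 =
  Bayes-optimal), lapse-extended fits, WAIC model comparison, and
  accuracy–sensitivity rank correlations. Sampling is done by a vectorized
  HMC with analytic gradients.
* **synthetic** — seeded cohort generation with planted decision policies
  (either logistic coefficients or observer parameters), emulating the
  structure of the human experiment (four groups, ~50 participants, ~500
  trials).
* **cli** — an `occam` command that orchestrates
  calibrate → generate → simulate → fit → report with YAML configs.

## Worked example

```python
import numpy as np
from occam.manifolds import PointManifold, SegmentManifold, NoiseModel
from occam.evidence import posterior_choice_prob, fia_breakdown

point   = PointManifold((0.0, 0.0))
segment = SegmentManifold((-0.5, 1.0), (0.5, 1.0))
noise   = NoiseModel(sigma=1.0, n_obs=1)
X = np.array([[0.0, 0.5]])            # one datum, equidistant from both

print(posterior_choice_prob((segment, point), X, noise, "exact"))
# 0.5102430168403175  -> the simpler point model is preferred

b = fia_breakdown(segment, X, noise, with_exact=True)
print(round(b.fia_log_evidence, 6), round(b.exact_log_evidence, 6))
# -2.003855 -2.003855  -> the FIA is exact for straight segments
```

The datum sits exactly between the two shapes, so their best fits are
equally good; the preference for the point (probability 0.510 rather than
0.5) is purely the Occam factor from integrating over the segment's
configurations.

Running the numbered drivers in `analysis/` reproduces the main tables —
for example `python analysis/01_calibrate_variants.py` prints

```
dimensionality sigma* = 3.2369   fresh gap =  0.99 pp   Bayes accuracy = 83.9%
boundary       sigma* = 3.1769   fresh gap =  1.03 pp   Bayes accuracy = 90.7%
volume         sigma* = 2.6848   fresh gap =  1.05 pp   Bayes accuracy = 90.8%
robustness     sigma* = 0.8391   fresh gap =  0.98 pp   Bayes accuracy = 93.7%
```

(the per-variant noise levels frozen in the shipped config, re-derived from
scratch and validated on fresh seeds), and
`python analysis/04_cohort_fit.py` fits a planted cohort and recovers its
population relative sensitivities.

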