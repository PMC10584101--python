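# rnfldecay

Circular statistics for high-resolution OCT retinal nerve fiber layer
(RNFL) profiles: direction-specific normative references, the Angular
Decay transform, "petal" tracing of focal loss, von Mises mixture
clustering of decay directions, and cluster-refined glaucoma
classification — with a seeded synthetic cohort generator so the whole
pipeline runs without clinical data.

## The problem

Spectral-domain OCT measures RNFL thickness at N = 256 equally spaced
angular points (every 1.41°) around a 3.46 mm circle centered on the
optic nerve head, indexed counterclockwise in TSNIT
(Temporal–Superior–Nasal–Inferior–Temporal) order. Conventional
analysis collapses this circular sequence into quadrant or clock-hour
averages and discards the directional information, even though
glaucomatous RNFL loss is typically focal — wedge defects concentrated
in the superior and inferior arcuate bundles. This package treats the
scan as what it is, circular data, and asks *in which direction* an
eye is losing tissue, not just how much.

## The method

**Normative catalog.** Normal eyes are stratified into 9 groups G by
age band (Age1 40–49, Age2 50–59, Age3 ≥ 60 years) and optic disc area
(Small < 1.6, Average 1.6–2.6, Large > 2.6 mm²). For each group and
each angular point j the empirical CDF of normal thickness is stored:

    eCDF_{G,j}(x) = |{r ≤ x : r ∈ R_{G,j}}| / |R_{G,j}|

giving 9 × 256 = 2304 direction-specific reference distributions.

**Angular Decay.** An eye i ∈ G is mapped pointwise to its normative
quantile, AngularQuantile(i,j) = eCDF_{G,j}(RNFL(i,j)), and its
complement AngularDecay = 1 − AngularQuantile ∈ [0,1]. Decay near 1 at
angle θ means the eye ranks at the very bottom of its normal
population in that direction.

**Petals and directional summaries.** At a quantile threshold τ
(default 0.75), each maximal circular run of points with decay > τ is
a *petal* Π; runs straddling the temporal origin are merged. Per eye:
ν = petal count; π* = widest petal; λ* = width(π*)/N (local loss);
Λ = Σ widths / N (global loss), with 0 ≤ λ* ≤ Λ ≤ 1; and

    μ* = atan2( Σ_{j∈π*} w_j sin θ_j , Σ_{j∈π*} w_j cos θ_j ),

the decay-weighted circular mean of π* — the eye's directional
signature of focal loss (NA when no petal exists).

**Clustering and classification.** The μ* angles of glaucomatous eyes
are fitted with mixtures Σ_k α_k vM(μ_k, κ_k) of von Mises
distributions by EM (κ via inversion of the Bessel ratio I₁/I₀); the
number of components is chosen by minimizing
BIC = −2ℓ + (3K − 1) ln n. Binary CART trees with
permutation-tested splits then classify glaucoma vs normal from the
loss indices, either on the pooled cohort or separately within each
circular cluster.

## Worked example

```python
import pandas as pd
import rnfldecay as rd

# a seeded synthetic cohort: 500 normal + 100 glaucomatous eyes with
# wedge defects clustered near 100 deg (superior) and 290 deg (inferior)
profiles, truth = rd.generate_cohort(500, 100, seed=1)
normals  = [p for p in profiles if p.status == "normal" and not p.excluded]
glaucoma = [p for p in profiles if p.status == "glaucoma" and not p.excluded]

ref = rd.NormativeReference().fit(normals)      # 2304 eCDFs
print(ref.catalog_.n_entries)                   # -> 2304

decay = ref.transform(glaucoma)                 # Angular Decay matrix
summary = rd.summarize_table(decay, tau=0.75)   # nu, mu*, lambda*, Lambda
print(summary[["nu", "mu_star", "lambda_star", "Lambda"]].head(3))

mu = summary["mu_star"].dropna()
fit = rd.select_K(mu.to_numpy(), seed=1)        # BIC over K = 1..5
print(fit.n_components, fit.means_deg_.round(1))
```

Output from this exact snippet:

```
2304
        nu     mu_star  lambda_star    Lambda
eye_id
G00001   6  302.945491     0.148438  0.175781
G00002  16  316.545254     0.230469  0.402344
G00003  14  270.262916     0.195312  0.289062
3 [  1.4 101.5 289.2]
```

Each glaucomatous eye gets a petal count ν, a decay direction μ*
(degrees), and its local/global loss fractions. The fitted mixture
weights are `[0.01 0.45 0.54]`: the two dominant components sit at
101.5° and 289.2° — the planted superior and inferior defect
directions, recovered from the decay pipeline alone — while the third
is a negligible background component collecting the few eyes whose
widest petal is noise rather than their defect. A command-line
interface mirrors the same chain (`rnfldecay simulate | build-catalog
| decay | petals | cluster | classify | plot`).

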