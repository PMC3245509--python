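# Methods

## The motion model

A protein fluctuating around a minimum-energy conformation is described
harmonically: the mean-square displacement of atom a is a sum over normal
modes, ⟨D_a²⟩ = Σ_k |D_ak|². `flexmotion`'s mode engine is a Cα anisotropic
network model (ANM): every pair of Cα atoms closer than a cutoff (default
13 Å) is connected by a Hookean spring with uniform force constant γ = 1.
The 3n × 3n Hessian is diagonalized densely (chains here are desk-scale,
n ≤ a few hundred); the six near-zero eigenvalues (< 1e-8 × the largest)
are the rigid-body modes and are discarded. More than six near-zero modes
means the contact network is disconnected or mechanism-like and the input
is rejected. Each remaining eigenvector u_k is scaled to its
root-mean-square thermal amplitude D_ak = √(k_BT/λ_k)·u_ak with k_BT ≡ 1
model unit: per-chain z-normalization downstream removes the absolute
scale, so only relative stiffness matters.

For every residue, the segment of 9 residues centered on it (truncated at
the termini, minimum 5; residues whose segment is shorter are masked) is
considered. For each mode, the displaced segment conformation
r⁰ + D_k is superposed onto the reference segment by the optimal rigid
motion (Kabsch, batched over modes); the per-atom displacement under that
rigid map is the *external* part D^e, the residual is the *internal* part
D^i, and D = D^e + D^i holds exactly by construction. Summing squares over
all modes and averaging over segment atoms yields per-residue
⟨|D^e|²⟩, ⟨|D^i|²⟩ and the interference term 2⟨D^e·D^i⟩; their sum equals
the total segment mean-square displacement to ~1e-15 relative error
(conservation is an identity, not an approximation). At the rigid-fit
optimum the interference term is tiny — median ≈ 0.05–0.2% of the first
two terms on generated 60-residue structures — which is what justifies
reporting external and internal motion as separate magnitudes.

Two caveats are worth recording. First, the decomposition of *finite*
displacements is not homogeneous in amplitude: scaling all mode amplitudes
by c does not leave the cross-term ratio exactly invariant (the fitted
rotation depends nonlinearly on the displacement). The ratio is invariant
under joint dilation of coordinates and displacements, and converges as
amplitudes shrink toward the harmonic regime; both properties are tested.
Second, with k_BT ≡ 1 the softest modes of an *under-packed* geometry can
reach amplitudes far beyond any harmonic validity; the synthetic generator
therefore rejects such geometries (below).

## Normalization, categories, classes

Raw magnitudes y'_i are z-normalized per chain, y_i = (y'_i − ȳ)/s (sample
SD), giving the normalized NMA score. Residues are grouped by mobility
(y > 1 high, y < −1 low, otherwise normal — boundaries to normal) to build
the mobility-propensity table Prop(n, g) = log₂ freq(n,g)/Σ_g freq(n,g),
where freq(n,g) is the relative frequency of amino acid n within group g.
Per group, propensities more than one SD above (below) the mean of the 20
values set the `<g>_high` (`<g>_low`) binary feature. On small corpora a
pseudo-count of 1 is added automatically when any (n, g) cell is empty, to
keep the logarithm finite; it is off for corpora that cover every cell.

Window-location categories come from the annotated secondary structure:
H and E residues count as "in secondary structure", maximal ss and non-ss
runs are found, and a residue ≥ 3 positions from both ends of its run is
CS (ss run) or RS (non-ss run); everything else is PS. Classes use the
per-category mean ± 1 SD of the normalized score pooled over the training
corpus: within one SD (inclusive) → intermediate, above → flexible, below
→ rigid. Terminal floor(W/2) residues are excluded — the geometric
consequence of a centered window.

## Encoding

Eighteen binary features per residue: 7 physicochemical (hydrophobic
{A,C,F,G,H,I,K,L,M,T,V,W,Y}, polar {C,D,E,H,K,N,Q,R,S,T,W,Y}, aromatic
{F,H,W,Y}, aliphatic {I,L,V}, small {A,C,D,G,N,P,S,T,V}, positive {H,K,R},
negative {D,E} — the classical classification, overridable in config),
6 mobility (from the propensity table), 3 secondary structure (one-hot from
the annotation), 2 ASA (exposed if ASA > 27, buried if < 11; preset (1, 3)
for class-coded inputs). Ordered feature pairs — 7×7 physicochemical, 6×6
mobility, the 3 ss diagonal pairs, 2×2 ASA = 92 — are evaluated with the
first feature on the window center and the second on each of the W − 1
partners, value = sum ∈ {0, 1, 2}: 920 variables at W = 11 (internal),
1,472 at W = 17 (external). Unknown residues (X, B, Z, U) get all-zero
identity features with a warning.

## Training and prediction

One `RandomForestClassifier` per category (defaults mirroring the classical
classification settings: 500 trees, √p candidate variables per split,
minimum node size 1; deterministic per seed, category index offsets the
seed). External motion trains two sub-models: the flexible-class windows
are split by the length of the y > 1 run containing them — ≤ 9 residues for
`external_short`, > 9 for `external_long` (the run-length histogram of
generated corpora peaks near 9, matching the premise) — and at prediction
time residues inside a long-model flexible run of > 9 residues take the
long model's scores.

The predicted class becomes a score via the per-cell statistics,
score = avg + SD·z. The z at prediction time is genuinely open — true
normalized scores are unknown for new sequences — so two policies are
implemented: the default z = 0 (cell mean), and an "expected-score" policy
Σ_class P(class)·avg_class using the forest's vote fractions. Scores are
smoothed by a 5-residue moving average that skips masked residues and
shrinks at the termini. Regions of ≥ 3 consecutive residues with smoothed
score > 1 are extracted as high-motion candidates (1-based inclusive
coordinates everywhere user-facing).

The naïve baseline scores residue i as −1.5·SD/(1 + d) + avg inside an ss
run and 3·SD/(1 + d) + avg otherwise, d the distance to the run center
(half-integer centers for even runs; helix and sheet runs are separate, so
a direct H→E transition ends a run). The published dataset constants
(avg 6.80e-6 / 7.49e-3, SD 1.00 / 1.01 for internal / external) are the
defaults.

## Assessment

Margin MAE: the per-residue error is max(0, |x − y| − margin) with margin
0.2 by default ("soft" semantics; a "hard" alternative charging the full
|x − y| outside the band is available because the original margin
arithmetic is ambiguous); margin 0 recovers Σ|x − y|/M exactly. Pearson CC
is averaged unweighted over chains where it is defined (constant
predictions are flagged, not fatal). ROC: positives are residues with
reference score above a threshold (1, 0, −1); the decision cutoff sweeps
−2…4 in 0.01 steps and AUC is the trapezoid area. The standard rates
TPR = TP/(TP+FN), FPR = FP/(FP+TN) are used; the sweep-based AUC agrees
with rank-based AUC to < 0.01 on all tested fixtures.

## Synthetic data: what it emulates and what it does not

`generate_toy_structure` realizes an H/E/C string with ideal local geometry
— helix: 1.5 Å rise/residue, 100° twist, 2.3 Å radius; strand: 3.4 Å-rise
zigzag; coil: self-avoiding 3.8 Å-step random walk — chaining runs with
random turns. Chains are steered toward a confinement radius of
3.2·n^(1/3) Å so they pack like globules (Rg ≈ 12 Å at n = 60), while coil
runs of ≥ 9 residues behave as *surface loops*: steered outward for their
first half and back for their second, so they keep few tertiary contacts
and are genuinely soft — the property the predictor is supposed to learn.
Terminal tails are short (3–5 residues). Gaussian coordinate jitter
(default SD 0.15 Å) breaks exact symmetry.

Sequences are drawn with probability 0.7 from ss-biased residue pools
(helix AELMQKRH, sheet VIFYWTC, coil GPSNDQ; uniform background otherwise),
which couples composition to mobility and gives the propensity features
signal. ASA is a geometric proxy — a per-chain linear decreasing map of the
10 Å neighbor count onto [0, 50] — because only the two binary threshold
features ever reach the model. The ss annotation equals the generating
string (perfect-predictor regime) or is corrupted at a configurable flip
rate (noisy-predictor regime).

Quality control: a drawn geometry occasionally leaves a quasi-mechanism —
a nearly free hinge whose softest eigenvalue is orders of magnitude below
the rest of the spectrum and whose k_BT-scaled amplitude leaves the
harmonic regime. Corpus generation rejects and deterministically resamples
structures whose softest/stiffest eigenvalue ratio is below 1e-5 (a
deliberately weak floor: soft surface loops must survive). The standalone
60-residue demonstration structure uses a stricter, size-referenced floor
(5e-4 at n = 60, scaled by (60/n)² since the softest eigenvalue of a
chain-like elastic body falls off as ~1/n²) because the cross-term bound is
a statement about the harmonic regime.

The default training corpus is 16 chains of 60–120 residues — small enough
to build in seconds, large enough that every (category, class) cell needed
for training is populated. What passing tests on this corpus shows: the
pipeline is self-consistent — labels derived from the network physics are
learnable from the sequence/annotation features, the trained forests beat
the naïve topological baseline, and planted long loops are recovered. What
it does not show: performance on real proteins, where annotations come
from imperfect predictors, side chains and packing produce motions a Cα
network cannot represent, and sequence–mobility coupling is weaker than
the generator's.

## Numerical choices

* Eigen-decomposition: dense `scipy.linalg.eigh`; zero-mode threshold
  1e-8 × largest eigenvalue; fewer than 6 near-zero modes (collinear
  geometry) is an error.
* Kabsch: batched SVD over modes with determinant correction on the
  smallest singular direction; collinear or < 3-point segments are
  rejected as under-determined.
* All statistics use the sample SD (ddof = 1).
* Boundary conventions: mobility-group boundaries (y = ±1) go to the
  normal group; class boundaries (exactly mean ± SD) go to intermediate.
* Random Forest determinism: `random_state = seed + category_index`;
  model bundles are serialized with joblib and round-trip bit-for-bit.
* Residue indexing is 1-based in every file format and report; internal
  arrays are 0-based.

## Known limitations

* The Cα network with uniform springs has no sequence dependence on the
  label side; all learnable signal flows through geometry and the
  generator's composition coupling.
* All 3n − 6 modes are summed (an optional top-m restriction exists); no
  entropy weighting beyond 1/λ.
* The per-chain ASA proxy is rank-preserving but not a physical solvent
  calculation.
* Internal-motion prediction requires chains longer than the 11-residue
  window plus exclusion zones; very short peptides are rejected.
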