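# Methods

## The decision problem

A Markov (row-stochastic) matrix `M` on `d ∈ {2, 3, 4}` states is
*embeddable* when `M = e^Q` for a rate matrix (Markov generator) `Q`, and
*g-embeddable* when it occurs in the solution flow of `dM/dt = M Q(t)`
for some locally integrable family of generators.  The package decides
the classic question completely for `d ≤ 4` and provides the standard
partial machinery for the generalised question at `d = 3`.

Two structural facts organise everything:

1. Any real logarithm `R` of `M` commutes with `M`.  When `M` is cyclic
   (minimal polynomial of full degree), its commutant is the polynomial
   ring in `M`, so every candidate is `R = Σ α_i A^i` with `A = M − I`,
   and the spectral mapping theorem turns `e^R = M` into a (possibly
   confluent) Vandermonde system in the shifted eigenvalues
   `μ_i = λ_i − 1`, one candidate per winding choice of the complex
   logarithm.  These systems are solved in closed form.
2. When a real eigenvalue is repeated with geometric multiplicity 2, the
   logarithm carries a two-parameter rotation freedom: in a real
   eigenbasis the repeated block may be `log|λ| I + θ_k I_{x,y,z}` with
   `I_{x,y,z} = [[x, −z], [y, −x]]`, `yz − x² = 1`, `z > 0`, and winding
   angle `θ_k = 2πk` (positive `λ`) or `(2k+1)π` (negative `λ`).

Winding enumerations are finite because generator eigenvalues lie in a
cone: `|Im z| ≤ −Re z · tan(π/2 − π/d)`, i.e. `|Im z| ≤ −Re z/√3` for
`d = 3` and `|Im z| ≤ −Re z` for `d = 4`.  (Sanity anchor: the extremal
3×3 circulant generator has eigenvalues `−π√3 ± iπ`, exactly on the
cone.)  A rotation carried by the Perron eigenvalue 1 would need a purely
imaginary non-zero generator eigenvalue, which the cone forbids; those
branches are skipped.

Every verdict of `embeddable` is backed by an explicit generator that
passes `‖e^Q − M‖_∞ ≤ 1e−8` (configurable).  `not_embeddable` is only
reported with a cited certificate (determinant/Culver/transitivity
failure, an empty winding range, or a unique candidate with a negative
rate).  When a heuristic search fails without a certificate the verdict
is `undecided_search`.

## Spectral classification

* Eigenvalues are clustered by single linkage at relative tolerance
  `cluster_tol` (default `1e−9 · ‖M‖`).  Geometric multiplicities come
  from the singular values of `M − λI` with threshold
  `max(1e−9 σ_max, 50 · cluster spread, 1e3 ε σ_max)`.
* Numerically computed eigenvalues of defective matrices split at scale
  `ε^{1/k}` (≈ `1e−8` for a Jordan 2-block, ≈ `1e−5` for a 3-block), so a
  fine clustering alone misclassifies every defective input.  When a
  coarser clustering at the defect tolerance `1e−5` (relative) merges
  additional eigenvalues, *both* Jordan hypotheses are solved and the
  results merged: any residual-verified generator settles the verdict,
  otherwise the fine-clustering verdict stands and the result is flagged
  `classification ambiguous at tolerance`.  This replaces a fragile
  either/or classification with a cheap enumeration of at most two
  hypotheses (the classification is discontinuous; no tolerance choice
  can be right on both sides of it).
* Matrices supplied as exact rationals (JSON `"exact"` entries) can be
  classified in exact arithmetic via sympy, removing the ambiguity for
  printed examples.

## The rotation-block search

`ixyz_feasibility` parametrises `(x, s)` with `z = e^s`,
`y = (1 + x²) e^{−s}` and maximises the minimum off-diagonal entry of the
candidate by Nelder–Mead from a 5×5 grid of starts on `[−3, 3]²`,
accepting when the optimum clears `−1e−9` (off-diagonal entries in
`[−1e−9, 0)` are then clipped to zero and the diagonal re-balanced).  A
successful search returns a verified generator; a failed search is
explicitly *not* a certificate, and uniqueness flags stay at
`search_incomplete` whenever a winding range was non-empty, unless a
Cuthbert certificate applies.  For a triple eigenvalue the rotated
2-plane inside the 3-dimensional eigenspace is itself a search variable
that we do not scan; only the fixed trailing plane of the computed
eigenbasis is explored, which is one reason the flag is conservative.

## Equal-input matrices with repeated negative eigenvalue (d = 3)

The only 3×3 Markov matrices with a repeated negative eigenvalue are the
equal-input matrices `M_c = (1 − c) I + C` with summatory parameter
`c ∈ (1, 3/2]`.  Any embedding generator lies in the four-dimensional
zero-row-sum commutant of `C` (basis `Q_1, Q_2, Q_3, R_0`) and must have
eigenvalues `−Δ ± (2k+1)πi` with `Δ = −log(c − 1)`.

Two closed-form generator families are constructed:

* the **stationary family** `Q_±` from the stationary point of the
  constrained eigenvalue problem, with decay exponent
  `Δ_stat = π κ √c / √(c₁c₂c₃)`, `κ = max c_i`;
* the **cyclic-support family** `t · [[−1/c₁, 1/c₁, 0], [0, −1/c₂, 1/c₂],
  [1/c₃, 0, −1/c₃]]` (and its reversed orientation), with
  `Δ_cyc = (σ/2) π / √(c/p − σ²/4)`, `σ = Σ 1/c_i`, `p = c₁c₂c₃`,
  defined when `c/p > σ²/4`.

Both commute with the central equal-input generator `Q_C = C − cI`, so a
boundary solution at exponent `Δ*` deforms to every interior parameter
via `Q + τ Q_C` with `τ = log((c* − 1)/(c − 1))/c*`, and higher winding
levels scale the construction by `2k + 1`.

For the uniform direction the two families coincide (both give
`Δ = π√3`, the two circulant generators, and `c_max = 1 + e^{−π√3}`),
and direct constrained minimisation over the commutant confirms this is
the true optimum.  For skewed directions the families differ, and —
contrary to a closed form sometimes quoted for this case — the
*stationary* family is not optimal: for direction `(1, 1, 2)` the cyclic
family reaches `Δ = 5.937 < 2π√2 = 8.886`, and its exponential matches
the corresponding equal-input matrix to `5e−16`; constrained SLSQP
minimisation finds no better exponent and reproduces exactly this value.
For direction `(1, 2, 3)` the numerical optimum (`π√5`) beats both
closed forms, so the package treats the union of the two families plus a
direct SLSQP feasibility search as a *constructive lower bound* on the
embeddable range, not as its exact boundary.  The only negative
certificate used is sound for every direction: the `d = 3` cone forces
`Δ ≥ π√3`, so `c > 1 + e^{−π√3}` is certified non-embeddable.  Between
the constructive region and that cap a failed search is reported as
`undecided_search`.  Uniqueness is claimed (`complete_finite_enumeration`)
only for the uniform direction.

## Substitution models

State order is fixed to (A, G, C, T); a `--order` flag permutes rows and
columns simultaneously.  Equal-input: embeddable iff `c < 1` for `d = 4`
(plus the `c > 1` branch above for `d = 3`), generator
`−log(1−c)/c · A`.  Tamura–Nei: spectrum
`{1, 1−Σa, 1−κ₁(a₁+a₂)−(a₃+a₄), 1−(a₁+a₂)−κ₂(a₃+a₄)}`; a simple TN
matrix is embeddable iff all three non-unit eigenvalues lie in `(0, 1)`,
and the unique generator (the principal logarithm) is verified to be
TN-shaped.  K3ST: spectrum `{1, 1−2(x+z), 1−2(y+z), 1−2(x+y)}`; simple
K3ST is embeddable iff all `λ_i > 0` and `λ_1 ≥ λ_2λ_3` cyclically, with
the unique generator assembled from quarter-sums of signed eigenvalue
logarithms and verified K3ST-shaped.  Fully degenerate parameter choices
route to equal-input; partially degenerate ones (HKY/K2P patterns) are
delegated to the general `d = 4` solver.

## Time-inhomogeneous flows

The convention is row-vector dynamics `dM/dt = M Q(t)`; piecewise-constant
families append exponential factors on the right
(`[(t₁, Q₁), (t₂, Q₂)] ↦ e^{t₁Q₁} e^{t₂Q₂}`) and are solved exactly as
segment products.  Callable families use the truncated Peano–Baker series
(`I_{n+1}(t) = ∫₀ᵗ I_n Q dτ`, cumulative trapezoids on a uniform grid,
truncation at `‖I_n‖_∞ < 1e−14` or 60 terms) with grid doubling from 64
points until two resolutions agree to `1e−10` (cap 4096).  The Liouville
deviation `max_t |det M(t) − exp(∫ tr Q)|` is reported with every
solution as an integration diagnostic.

The `d = 3` g-embeddability cascade: (i) Goodman's inequality
`∏ m_ii ≥ det M > 0` is necessary — its failure is the only
`not_g_embeddable` certificate issued; (ii) with a zero off-diagonal
entry it is also sufficient (at most 5 Poisson factors); (iii) totally
positive with `B_M ≥ det M` is sufficient (at most 6 factors), where
`B_M = max_{i,j} (m_ii m_jj / m_ij)(−1)^{i+j+δ_ij−1} M^{(ij)}`;
(iv) classic embeddability implies g-embeddability; (v) otherwise the
report is `undecided` with the determinant-bracket factor bound
(`5k−2` / `5k−1`) attached when applicable.  The complete criterion in
the remaining region depends on an inequality system not implemented
here; the package never converts a failed search into a negative verdict.

## Seeded random instances

`sample_generator(d, seed, style)` draws off-diagonal rates
`Exp(1)/(d−1)` (one expected event per unit time per state — the usual
normalisation of substitution models), with `equal_input`, `tn`, `k3st`
and `poisson_mix` styles respecting their defining shapes.  These probe
the generic (simple-spectrum) strata heavily and the degenerate strata
not at all — degenerate Jordan patterns are exercised instead by exact
structured fixtures (absorbing chains with tied rates, Kronecker
products, block sums).  Passing round-trip tests therefore demonstrates
correctness on generic matrices and on exactly degenerate ones, but says
little about *near*-degenerate inputs (eigenvalue gaps around `1e−6`),
where classification is intrinsically ill-conditioned and results carry
the ambiguity flag.

## Numerical parameters

| parameter | default | role |
|---|---|---|
| `tol` (validation) | `1e−9` | row sums, sign clamping |
| `cluster_tol` | `1e−9` (rel.) | eigenvalue clustering |
| defect tolerance | `1e−5` (rel.) | second Jordan hypothesis |
| residual contract | `1e−8` (∞-norm) | acceptance of any generator |
| search accept | `−1e−9` | min off-diagonal at the optimum |
| winding cap | `k ≤ 50` | guard for tiny eigenvalues |
| PBS truncation | `1e−14` / 60 terms | series tail |

Degenerate boundaries (eigenvalues within tolerance of 0 or of the
negative real axis) are treated conservatively: the principal logarithm
is declared undefined and determinant-style certificates fire, matching
the strict `det M > 0` requirement.

## Known limitations

* Winding searches are heuristic in one direction: generators they find
  are certified, generators they miss are not excluded.  Uniqueness
  flags distinguish `unique_certified`, `complete_finite_enumeration`
  and `search_incomplete` accordingly.
* The exact embeddability boundary for skewed equal-input directions
  with `c > 1` (d = 3) is, to our numerical evidence, *not* given by the
  stationary closed form; the package brackets it between its
  constructive families and the `π√3` cone cap (see above).
* For the Jordan pattern `diag(1, 1, λ, λ)` with `λ < 0` the package
  certifies exclusion below `−e^{−π}` and searches above it; we found no
  strictly feasible generator for any instance of this pattern (direct-sum
  constructions provably admit none), so positive verdicts here, if they
  exist, require inputs engineered for the search to succeed.
* d = 4 g-embeddability is out of scope beyond the necessary conditions;
  `d > 4` is not supported.
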