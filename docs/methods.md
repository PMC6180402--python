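# Methods

## Problem and model

A data holder owns N records (x_i, y_i), x_i a vector of D small
integer features with a leading 1 for the bias, y_i ∈ {0,1}.  The
logistic model scores Pr(Y | x) through σ(wᵀx), σ(t) = 1/(1+e^{−t});
the label convention is that y = 1 marks the class whose posterior is
σ(wᵀx), and the gradient formula below is taken as the ground truth.
Training is full-batch gradient descent

    w ← w − α (σ(Xw) − y) Xᵀ,

or its 1-bit variant: u = g + β·residue, w ← w − α·sign(u),
residue ← u − α·sign(u), with sign(0) = 0.  The residue recurrence has
two defensible readings; we take "decay applied to the stored residue"
(u = g + β·residue) as normative, and the plaintext trainer exposes
`residue_strategy="decay_after"` (residue ← β(u − α·sign(u))) for
comparison.

All of this must run over FV ciphertexts, where only +, × and slot
rotations exist, plaintexts are integers modulo t = p^r, and every
operation grows ciphertext noise.

## Fixed point in balanced base p

Rationals are scaled to x̃ = round(p^f x) and reduced centred modulo
p^r, r = l + 2f: l integral digits, f fractional, and f spare digits so
one product can be held before rescaling.  Digits are balanced
(in [−(p−1)/2, (p−1)/2]), so the most significant digit carries the
sign.  The canonical rescale drops the lowest balanced digit:

    scale(x̃) = (x̃ − (x̃ mod* p)) / p = round(x̃ / p),

where mod* is the centred remainder; p odd means no ties, so this is
exact round-to-nearest.  We use the *same* balanced-drop convention in
the plaintext codec and in the homomorphic bscale, which is what makes
plaintext oracle and encrypted path agree bit for bit (the digit-removal
polynomials of the bootstrap are intrinsically balanced-digit
operations, and sign extraction = most-significant-digit only holds in
this convention).  Scaling may be deferred across a multiply-accumulate
and applied once to the sum.

Constants are prepared with floor (σ₃'s coefficients: ⌊0.5p²⌋ = 8064,
⌊0.197p⌋ = 25, ⌊0.063p⌋ = 8 at p = 127) or round (the learning-rate
digit round(√α·p), e.g. √0.002 ≈ 0.0447 → 6), matching the two
conventions the worked constants use.

## Batching and rotations

With p coprime to 2n, x^n + 1 factors into k = n / ord_2n(p) distinct
irreducible polynomials mod p; Hensel lifting carries the factorisation
to p^r and the CRT idempotents give k SIMD slots.  Slots are Galois
rings for k < n; the pipeline stores only integer (degree-0) slot
content, which is all training needs, and the codec rejects anything
else.  Slot order is fixed along the orbit of a rotation generator
(default Galois exponent 3) at codec construction.  Because the
automorphism group of a power-of-two cyclotomic is Z₂ × Z_{n/2} (almost
never cyclic), a cyclic rotation by j is realised as at most two Galois
automorphisms glued with 0/1 plaintext masks; `sumslots` needs only
rotations by powers of two — exactly log₂k of them.

## bscale: bootstrapping fused with rescaling

Goal: from an encryption of m (mod p^r), obtain a *low-noise*
encryption of round(m/p) (mod p^r).  Single-digit pipeline:

1. slots → coefficients (a homomorphic linear transform: k masked
   rotations applying the slot-evaluation Vandermonde);
2. free division: retag the ciphertext at plaintext modulus p^{r−1}
   (zero cost; the dropped digit becomes noise);
3. modulus-switch to q′ = p^{e−1}; the integer wrap b·t of the
   decryption identity survives reduction mod p^e as the upper garbage
   p^{e−1}·α;
4. dot product with the bootstrapping key (an encryption of s under
   plaintext modulus p^e at full q): each coefficient now holds
   M = v + p^{e−r}·round(m/p) + p^{e−1}·α (mod p^e), |v| ≤ p^{e−r}/2;
5. coefficients → slots (inverse transform at p^e), then e−r rounds of
   {evaluate the one-digit-removal polynomial, free-divide by p}.  A
   single polynomial removing j ≥ 2 digits mod p^e does not exist —
   this is checkable: sequential Newton (Mahler-basis) interpolation is
   a sound decision procedure for "is this function a polynomial mod
   p^e", and it refutes the two-digit remover at (p,e) = (3,3), (5,3),
   (3,4), (5,4) in both digit conventions — so removal and exact
   division must interleave, as in the digit-extraction literature;
6. strip α: digit 0 of the current value is x − remove1(x), clean;
   the remaining digits are recovered recursively at the next-lower
   modulus and re-merged through a garbage-free modulus-raising
   bootstrap (mod-switch to q′ = p^e exactly, where b·q′ ≡ 0 mod p^e,
   so no α appears).

bscale(·, i) iterates the single-digit pipeline i times; dropping one
balanced digit i times equals dropping i digits, by uniqueness of the
balanced expansion.  Sign extraction is bscale(·, r−1).

**Digit polynomials.** The one-digit remover mod p^e is built by
sequential Newton interpolation on the points 0, 1, 2, …: the Newton
coefficient at point d must satisfy c_d·d! ≡ residual (mod p^e), which
pins c_d up to an ambiguity that provably does not affect values.  The
construction terminates at degree (e−1)(p−1)+1 — e.g. 81 for p = 17,
e = 6 — far below the worst-case e·p^j bound, because any function
representable mod p^e has a canonical representative of degree
< min{d : p^e | d!} ≈ e·p.  Polynomials are verified against the digit
oracle over *all* residues when p^e ≤ 2·10⁵ and on a 4096-point sample
otherwise (the toy presets used by the exhaustive tests are all in the
full-verification regime).  Homomorphic evaluation is
Paterson–Stockmeyer (≈ 2√d ciphertext products).

**Choosing e.**  After step 4 the bound |v| ≤ p^{e−r}/2 must hold
against p^{e−r−1}·(ρ + v_f) + δ, where ρ is the digit dropped by the
free division, v_f the input noise and δ = mod-switch rounding with
|δ| ≤ (1 + ‖s‖₁)/2.  The slack is p^{e−r−1}/2, and we take the smallest
e with p^{e−r−1}/2 ≥ 2·δ_max: e = 5 for the p = 3 preset (n = 2), e = 4
for p = 5, e = 6 for the p = 17 training preset (n = 8, δ_max = 4.5,
17/2 < 9 but 289/2 ≥ 9).

## Parameter presets

| preset | n | q | p | r | e | k | role |
|---|---|---|---|---|---|---|---|
| toy-p3 | 2 | 2^400 | 3 | 2 | 5 | 1 | exhaustive bscale sweep, k=1 Galois-ring slot |
| toy-p5 | 2 | 2^400 | 5 | 2 | 4 | 2 | exhaustive bscale sweep, fully split |
| toy-train | 8 | 2^1600 | 17 | 3 | 6 | 8 | end-to-end encrypted training |
| toy-batch | 16 | 2^240 | 97 | 2 | — | 16 | batching playground |
| toy-subfield | 8 | 2^240 | 3 | 2 | — | 2 | k < n codec path |
| idash-shape | 2^15 | ≈2^1020 (17×60-bit primes) | 127 | 3 | 5 | 64 | full-scale configuration, never key-generated in tests |

q at toy scale is a single power of two held as a Python integer; the
toy-train value 2^1600 covers the worst noise path inside one bscale
(four sequential degree-≈(e−1)(p−1) polynomial evaluations, each
multiplying noise by ≈ 2·n·t per multiplicative level).  σ[χ] = 3.2
(discrete Gaussian by rejection from a 6σ-truncated range), secrets
ternary, relinearisation in base 2^64.  All randomness flows through
one injected seeded generator.

## Sigmoid approximation

Remez exchange with Chebyshev-node initialisation, multi-point
exchange, mpmath linear solves at 50 significant digits, convergence
when the levelled error stabilises to 1e−12.  On [−5, 5] the converged
coefficients are σ₁: (0.5, 0.125) and σ₃: (0.5, 0.197513, 0,
−0.004265); the printed three-decimal reference values truncate rather
than round the linear cubic-case coefficient, so comparisons are made
within one unit of the printed precision.  Over ciphertexts, σ₃'s
quantisation error is bounded by (3 + |x|)·p^{−f}/2 — three bscale
roundings, one re-multiplied by x̃ — which is the bound the tests
assert (the naive 2·p^{−f} is violated at the interval edge: at x = 5,
p = 127, the integer oracle gives 123/127 ≈ 0.9685 vs σ₃(5) = 0.985).

## Encrypted training circuit

Features are encrypted raw (scale p⁰, small integers), weights and
labels at scale p^f; a product x·w̃ then already sits at the sigmoid
input scale, so the inner product needs no rescale and the only
bscale-carrying steps are the sigmoid evaluation and the learning-rate
multiplication.  Per iteration: for each block of k samples,
z = Σ_j X_j ⊗ w_j; s = σ̃(z); d = (s ⊖ ỹ) masked on the padded tail of
the last block; Δ_j accumulates sumslots(d ⊗ X_j).  The weight update
packs k of the constant-vector Δ_j into one ciphertext (combine),
applies bscale(ã·bscale(ã·x̃)) once, and unpacks (expand via
sumslots) — reducing D scalings to ⌈D/k⌉.  The 1-bit path instead runs
u_j = Δ_j ⊕ bscale(β̃·residue_j), extracts sign(u_j) homomorphically,
and applies α̃·sign by a plain multiplication.  The caller must keep
|u_j| < 3p^{r−1}/2 so the most significant digit is in {−1, 0, 1}; the
toy training configurations are sized accordingly (the sign of a small
gradient extracts as 0 = no update, consistently in oracle and
circuit).

The trace emulator executes the same circuit on plain slot values and
charges the one-shot degree formulas e·r·p^{e−i} per bscale and
e·r·p^{e−r+1} per sign extraction — the standard cost accounting for
the fused operation, under which sign extraction is cheaper than a full
fixed-point rescale whenever f < r−1 (at f = r−1 they coincide).

## Synthetic data: what it does and does not show

The generator draws binary (optionally wider-range integer) features
uniformly and labels from Pr(y=1|x) = σ(b + w*ᵀx) with optional flip
noise; the default shape (N = 1579, D = 18 binary features) mirrors the
genomic task the method targets, and a reduced preset (N = 64, D = 4)
serves the encrypted path.  An image-compression helper reproduces the
handwritten-digit preprocessing: pixel ÷ 32 (integer floor) then 2×2
average pooling (floored), 196 features in [0, 8).  Synthetic features
are independent — no linkage structure, no class imbalance beyond what
w* induces, no missingness — so passing tests demonstrate the
*arithmetic* fidelity of the encrypted pipeline and the statistical
sanity of the trainers, not clinical-grade predictive performance on
real cohorts.  Real-data cross-validated AUCs and wall-clock timings at
n = 2^15 are outside desk scope.

Evaluation: AUC as the Mann–Whitney rank statistic (ties ½),
cross-checked in tests against an independent trapezoidal-ROC
implementation; 10-fold CV over a seeded shuffle, erroring (with the
fold named) if a held-out fold is single-class.

## Numerical choices and degenerate inputs

* Centred representatives [−m/2, m/2); rounding half away from zero;
  balanced remainders are tie-free because every p-power modulus is odd.
* Polynomial multiplication: schoolbook negacyclic convolution
  (canonical, n ≤ 64); an NTT kernel is cross-checked bit-exactly where
  the modulus supports it.
* The k = 1 bootstrapping path (n = 2) extracts the constant
  coefficient by the two-element Galois trace (P + τ₋₁P)/2 instead of
  the Vandermonde transform.
* Remez: a numerically-zero error curve (target already a polynomial of
  degree ≤ d) falls back to an evenly spaced reference and converges on
  the next sweep.
* decrypt of an over-noisy ciphertext silently returns a wrong value
  (undetectable without ground truth); tests use the exact noise
  functional and an `is_valid` helper instead.

## Known limitations

* Toy ring dimensions only (n ≤ 32 exercised); no RNS/double-CRT, no
  NTT-based performance engineering, no multithreading, no security
  estimation — the full-scale preset is configuration, not a claim.
* Real-backend bootstrapping requires a fully-splitting codec or k = 1;
  k < n presets with k > 1 bootstrap on the trace backend only.
* The serialisation container stores secret keys beside public material:
  this artifact is a correctness testbed, not a deployment.
* Mini-batch/stochastic variants exist in the plaintext trainers only;
  the encrypted path is full-batch by design.
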