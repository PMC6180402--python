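# fhelogit

Training logistic regression **on homomorphically encrypted data**, end
to end: a data holder encrypts a table of patient records (e.g. binary
genotype features and a disease phenotype), an untrusted party runs
gradient descent directly on the ciphertexts, and the data holder
decrypts an updated model — neither the records nor the trained weights
are ever visible to the party doing the computation.

The package is an exact-arithmetic implementation of that pipeline at
desk scale, built so that every encrypted computation can be checked
bit for bit against a plaintext oracle:

* **FV (Fan–Vercauteren) scheme** over R_q = Z_q[x]/(x^n+1): key
  generation, encryption, ⊕/⊗, relinearisation, Galois rotations, and
  *exact* noise measurement — decryption is correct iff the noise
  polynomial v in (t/q)(c0 + c1·s) = m + v + bt has ‖v‖∞ < 1/2.
* **SIMD batching**: with t = p^r and p coprime to 2n, R_t ≅ k-fold
  product of slots (k = n / ord_2n(p)); one ciphertext holds one
  feature across k samples ("vertical" encoding), so per-feature inner
  products are a slot-wise multiply plus `sumslots` (log₂k rotations).
* **Balanced base-p fixed point**: x = Σ x_i p^i with digits in
  [−(p−1)/2, (p−1)/2], stored as x̃ = round(p^f x) mod p^r, r = l + 2f.
* **bscale — bootstrapping fused with rescaling**: one operation that
  refreshes ciphertext noise *and* drops the lowest balanced digit
  (divides by p), built from free division, modulus switching, a dot
  product with an encrypted secret key, and digit-removal polynomial
  evaluations.  Homomorphic sign extraction is bscale(·, r−1): the sign
  of a fixed-point number is its most significant balanced digit.
* **Minimax sigmoids** by the Remez exchange algorithm on [−5, 5]:
  σ₁(x) = 0.125x + 0.5 and σ₃(x) = −0.004x³ + 0.197x + 0.5 (printed to
  three decimals), evaluated over ciphertexts as
  `bscale(8064 + 25·x̃ − bscale(bscale(8·x̃)²)·x̃)` at p = 127.
* **Two trainers**: full gradient descent `w ← w − α(σ(Xw) − y)Xᵀ` with
  σ₃, and 1-bit gradient descent (only the *sign* of each gradient
  coordinate reaches the weights; the remainder feeds a residue with
  decay β) with σ₁, where sign extraction is much cheaper than a full
  homomorphic rescale.

Every encrypted program runs on two interchangeable backends: the real
FV pipeline, and a trace emulator carrying plain slot values plus the
consumed degree budget.  Tests assert *exact* trajectory equivalence —
decrypted weights equal the plaintext fixed-point trainer coordinate
for coordinate, iteration for iteration.

## Worked example

Generate a synthetic genotype-style dataset (400 samples, 6 binary
features, labels from a ground-truth logistic model), train, and
cross-validate:

```text
$ fhelogit synth --n 400 --d 6 --seed 7 --out geno.csv
synthetic dataset N=400 D=6 seed=7 -> geno.csv

$ fhelogit train --data geno.csv --backend float --sigmoid s3 \
      --iterations 40 --alpha 0.0022
weights: [-0.5061, 1.4974, -2.2922, -0.4084, 0.1441, -0.5068, -0.3771]

$ fhelogit evaluate --data geno.csv --folds 10 --iterations 40 --alpha 0.0022
fold AUCs: [0.9373, 0.8763, 0.967, 0.9749, 0.8856, 0.9516, 0.9765, 0.9498, 0.9373, 0.842]
mean AUC: 0.9298
```

The first weight is the bias; the remaining six estimate the
ground-truth effect of each genotype.  The mean cross-validated AUC of
0.93 says a random case outranks a random control 93% of the time.

The same data can be trained under encryption (toy ring, n = 8, p = 17,
k = 8 slots) or on the trace emulator — the two produce identical
fixed-point weights:

```text
$ fhelogit train --data geno.csv --backend trace --preset toy-train \
      --algorithm gd --iterations 2 --alpha 0.04
weights: [-0.8235, -1.2941, -0.5294, 1.2353, 0.2353, 1.1765, 0.2353]
```

(These are scaled integers w̃/p after two fixed-point iterations at
base p = 17 — coarse, as a two-iteration toy run should be.)

The minimax sigmoid coefficients themselves:

```text
$ fhelogit remez --degree 3
{
  "degree": 3,
  "coefficients_ascending": [0.5, 0.19751289..., 0.0, -0.00426518...],
  "max_error": 0.0388904783401321
}
```

## Layout

| module | contents |
|---|---|
| `fhelogit.ring` / `fhelogit.fv` | negacyclic ring arithmetic (schoolbook + NTT kernels) and the FV scheme |
| `fhelogit.batching` | slot codec: CRT factorisation, Hensel lifting, rotation plans |
| `fhelogit.fixedpoint` | balanced base-p fixed point, the plaintext rescaling oracle |
| `fhelogit.bootstrap` | digit-removal polynomials, bscale, sign extraction, the two backends |
| `fhelogit.remez` | minimax approximation (Remez exchange, 50-digit arithmetic) |
| `fhelogit.training` | float / fixed-point / encrypted trainers, sumslots, combine/expand |
| `fhelogit.data` | synthetic generator, pooling compression, AUC, k-fold CV, CSV I/O |
| `fhelogit.serialize` / `fhelogit.cli` | JSON containers and the `fhelogit` command |

See `docs/methods.md` for the model, the bootstrapping pipeline, and
the numerical design choices.
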