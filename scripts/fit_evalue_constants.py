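"""Fit Karlin-Altschul (lambda, K) for the package's two scoring schemes.

Local-alignment scores of random sequence pairs follow an extreme-value
law P(S >= x) = 1 - exp(-K m n exp(-lambda x)). We simulate null pairs,
fit a Gumbel by maximum likelihood and convert: lambda = 1/scale,
K = exp(loc/scale) / (m n). The fitted values are frozen in
src/telotrace/_evalue_constants.py so that E-values are reproducible
without re-simulation.

Run from the repository root:  python scripts/fit_evalue_constants.py
"""

from pathlib import Path

import numpy as np
from scipy import stats
from Bio import Align
from Bio.Align import substitution_matrices

M = N = 128
N_DNA = 20_000
N_PROT = 8_000
SEED = 20_220_914  # fixed; the constants are part of the package definition

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def dna_aligner():
    a = Align.PairwiseAligner(mode="local")
    a.match_score, a.mismatch_score = 2, -3
    a.open_gap_score, a.extend_gap_score = -7, -2
    return a


def prot_aligner():
    a = Align.PairwiseAligner(mode="local")
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score, a.extend_gap_score = -12, -1
    return a


def fit(aligner, alphabet, n_trials, rng):
    letters = np.array(list(alphabet))
    scores = np.empty(n_trials)
    for i in range(n_trials):
        a = "".join(letters[rng.integers(0, len(letters), M)])
        b = "".join(letters[rng.integers(0, len(letters), N)])
        scores[i] = aligner.score(a, b)
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    k = float(np.exp(loc / scale) / (M * N))
    return lam, k, scores


def main():
    rng = np.random.default_rng(SEED)
    dna_lam, dna_k, _ = fit(dna_aligner(), "ACGT", N_DNA, rng)
    prot_lam, prot_k, _ = fit(prot_aligner(), AA20, N_PROT, rng)
    out = Path(__file__).resolve().parent.parent / "src" / "telotrace" / "_evalue_constants.py"
    out.write_text(
        '"""Karlin-Altschul constants fitted by scripts/fit_evalue_constants.py.\n\n'
        f"Null model: uniform random pairs of length {M} x {N}; "
        f"{N_DNA} DNA and {N_PROT} protein trials, RNG seed {SEED}.\n"
        '"""\n\n'
        f"DNA_LAMBDA = {dna_lam!r}\n"
        f"DNA_K = {dna_k!r}\n"
        f"PROT_LAMBDA = {prot_lam!r}\n"
        f"PROT_K = {prot_k!r}\n"
    )
    print(f"DNA:     lambda={dna_lam:.4f}  K={dna_k:.4g}")
    print(f"protein: lambda={prot_lam:.4f}  K={prot_k:.4g}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
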