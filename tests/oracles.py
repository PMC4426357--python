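"""Independent oracles for the obligate-single-crossover cross model.

Everything here is implemented from the model definition alone, without
importing any hawmap simulation code, so agreement between these numbers
and the package is evidence and not circularity.

Model (per chromosome of genetic length L cM): a gamete is a whole
parental chromosome (N2 or HAW, equiprobably) with probability 1/2;
otherwise it carries exactly one exchange at a position uniform in cM,
with random orientation.  Pooled lines are homozygous N2 at the causal
locus g0, so each contributes two gametes conditioned on N2-at-g0.
"""

from __future__ import annotations

import numpy as np

# --- conditional gamete, derived by hand from the model --------------------
#
# Unconditional gamete law:
#   P(whole N2) = P(whole HAW) = 1/4
#   recombinant: density (1/2) * (1/L) du over breakpoints, orientation 1/2
# Conditioning on N2 at g0 removes whole-HAW and the recombinant
# orientation with HAW over g0, leaving:
#   P(whole N2 | N2 at g0)             = 1/2
#   P(breakpoint in du, HAW away side) = du / (2 L)


def sample_conditioned_gamete(rng: np.random.Generator, g0: float, L: float):
    """HAW-carrying cM interval of one gamete conditioned on N2 at g0.

    Returns (lo, hi): the gamete is HAW on [lo, hi] and N2 elsewhere;
    (None, None) for a whole-N2 gamete.
    """
    if rng.random() < 0.5:
        return (None, None)
    u = rng.uniform(0.0, L)
    if u > g0:
        return (u, L)
    return (0.0, u)


def mc_gap_widths_cm(
    rng: np.random.Generator, n_lines: int, g0: float, L: float, reps: int
) -> np.ndarray:
    """Monte-Carlo widths (cM) of the zero-HAW gap around g0 for pools of
    ``n_lines`` lines (2 conditioned gametes each)."""
    widths = np.empty(reps)
    for r in range(reps):
        left, right = 0.0, L
        for _ in range(2 * n_lines):
            lo, hi = sample_conditioned_gamete(rng, g0, L)
            if lo is None:
                continue
            if lo == 0.0:  # HAW on [0, u], u < g0
                left = max(left, hi)
            else:  # HAW on [u, L], u > g0
                right = min(right, lo)
        widths[r] = right - left
    return widths


def enumerate_haw_freq(d_cm: float, g0: float, L: float, grid: int = 200_001) -> float:
    """P(HAW at a marker ``d_cm`` right of g0 | N2 at g0), by enumerating
    breakpoint positions on a fine grid (no closed form assumed)."""
    g1 = g0 + d_cm
    if not (0.0 <= g1 <= L):
        raise ValueError("marker outside the chromosome")
    u = np.linspace(0.0, L, grid)
    # recombinant branch, HAW on the side away from g0:
    #   u > g0 -> HAW on [u, L]: marker HAW iff g1 >= u
    #   u < g0 -> HAW on [0, u]: marker HAW iff g1 <= u (impossible, g1 > g0)
    haw = (u > g0) & (g1 >= u)
    # breakpoint density du/(2L); whole-N2 branch contributes 0
    return float(np.trapezoid(haw.astype(float), u) / (2.0 * L))


def mc_haw_freq(
    rng: np.random.Generator, d_cm: float, g0: float, L: float, n_gametes: int
) -> float:
    """Monte-Carlo version of :func:`enumerate_haw_freq`."""
    g1 = g0 + d_cm
    hits = 0
    for _ in range(n_gametes):
        lo, hi = sample_conditioned_gamete(rng, g0, L)
        if lo is not None and lo <= g1 <= hi:
            hits += 1
    return hits / n_gametes


# --- brute-force translation oracle ---------------------------------------

_CODON_MAP = {}


def _build_codon_map():
    # hand-entered standard nuclear code, grouped by amino acid
    groups = {
        "F": ["TTT", "TTC"],
        "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
        "I": ["ATT", "ATC", "ATA"],
        "M": ["ATG"],
        "V": ["GTT", "GTC", "GTA", "GTG"],
        "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
        "P": ["CCT", "CCC", "CCA", "CCG"],
        "T": ["ACT", "ACC", "ACA", "ACG"],
        "A": ["GCT", "GCC", "GCA", "GCG"],
        "Y": ["TAT", "TAC"],
        "*": ["TAA", "TAG", "TGA"],
        "H": ["CAT", "CAC"],
        "Q": ["CAA", "CAG"],
        "N": ["AAT", "AAC"],
        "K": ["AAA", "AAG"],
        "D": ["GAT", "GAC"],
        "E": ["GAA", "GAG"],
        "C": ["TGT", "TGC"],
        "W": ["TGG"],
        "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
        "G": ["GGT", "GGC", "GGA", "GGG"],
    }
    for aa, codons in groups.items():
        for c in codons:
            _CODON_MAP[c] = aa


_build_codon_map()
assert len(_CODON_MAP) == 64


def oracle_translate(seq: str) -> str:
    """Translate a CDS codon-by-codon ('*' for stops)."""
    if len(seq) % 3:
        raise ValueError("CDS length not a multiple of 3")
    return "".join(_CODON_MAP[seq[i : i + 3]] for i in range(0, len(seq), 3))


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def oracle_snv_effect(cds: str, idx: int, new_base: str) -> str:
    """Effect class of substituting ``new_base`` at CDS index ``idx``
    (0-based, coding strand), by translating the whole protein."""
    before = oracle_translate(cds)
    after = oracle_translate(cds[:idx] + new_base + cds[idx + 1 :])
    ci = idx // 3
    if before[ci] == after[ci]:
        return "synonymous"
    if after[ci] == "*":
        return "nonsense"
    if before[ci] == "*":
        return "stop_loss"
    if ci == 0 and before[ci] == "M":
        return "start_loss"
    return "missense"


def oracle_single_substitution_possible(
    aa_from: str, aa_to: str, nt_from: str, nt_to: str
) -> bool:
    """Brute force over all 64 codons and both strands: can a single
    genomic ``nt_from -> nt_to`` change turn ``aa_from`` into ``aa_to``?

    Amino acids are 1-letter codes ('*' for stop).
    """
    changes = [(nt_from, nt_to), (_RC[nt_from], _RC[nt_to])]
    for codon, aa in _CODON_MAP.items():
        if aa != aa_from:
            continue
        for f, t in changes:
            for i in range(3):
                if codon[i] != f:
                    continue
                mutated = codon[:i] + t + codon[i + 1 :]
                if _CODON_MAP[mutated] == aa_to:
                    return True
    return False
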