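"""Single-molecule PAIR analysis: correlated co-modification between
3-nt windows as direct evidence of RNA duplexes.

Molecules in which a helix is transiently open acquire DMS modifications
on both of its strands in the same read; across many reads this shows up
as a statistical excess of co-modification between the two complementary
windows.  The pipeline: exact 2x2 contingency counts for every window
pair, a co-modification count cutoff (n11 >= 10), a G-test of
independence with Bonferroni correction, a sequence-complementarity
requirement, and reactivity-threshold classification into principal
(window mean reactivity >= 0.4 and mutually strongest partner) and minor
(>= 0.2) PAIRs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .mutation_data import NO_DATA, ReadRecord, classify_event
from .reactivity import ReactivityProfile
from .structure_io import CANONICAL_PAIRS, ReferenceStructure

__all__ = [
    "WindowPair",
    "PairClass",
    "window_contingency",
    "g_statistic",
    "pair_correlations",
    "pair_ppv_sens",
    "write_pair_tsv",
]

WINDOW = 3
MIN_COMOD = 10  # co-modification count cutoff
MINOR_REACTIVITY = 0.2
PRINCIPAL_REACTIVITY = 0.4
# a PAIR asserts a 3-bp duplex: all 3 antiparallel positions must be able
# to pair (WC or GU), and the strands need at least a minimal hairpin
# loop between them
MIN_COMPLEMENTARY = 3
MIN_LOOP = 3


class PairClass(enum.Enum):
    PRINCIPAL = "principal"
    MINOR = "minor"
    REJECTED = "rejected"


@dataclass
class WindowPair:
    """A candidate correlation between 3-nt windows starting at i and j.

    Contingency counts are over reads covering both windows with valid
    data: n11 = modified in both, n10 = only window i, n01 = only window
    j, n00 = neither.
    """

    i: int
    j: int
    n11: int
    n10: int
    n01: int
    n00: int
    g_stat: float = 0.0
    p_corrected: float = math.nan
    pair_class: PairClass = PairClass.REJECTED
    reason: str = ""

    @property
    def depth(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def _read_matrices(
    reads: list[ReadRecord], length: int, mode: str = "dms"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-read boolean (mutated, valid) matrices after signature filtering."""
    n = len(reads)
    mut = np.zeros((n, length), dtype=bool)
    valid = np.zeros((n, length), dtype=bool)
    for row, read in enumerate(reads):
        lo, hi = read.span_start - 1, read.span_end
        if read.valid is None:
            valid[row, lo:hi] = True
        else:
            valid[row, lo:hi] = read.valid
        for ev in read.events:
            if classify_event(ev, mode) is NO_DATA:
                valid[row, ev.left - 1 : ev.right] = False
            else:
                for pos in ev.changed_positions():
                    mut[row, pos - 1] = True
    return mut & valid, valid


def _sliding_all(arr: np.ndarray, w: int) -> np.ndarray:
    """Row-wise: out[:, k] = all(arr[:, k:k+w]) for each window start k."""
    out = arr[:, : arr.shape[1] - w + 1].copy()
    for off in range(1, w):
        out &= arr[:, off : arr.shape[1] - w + 1 + off]
    return out


def _sliding_any(arr: np.ndarray, w: int) -> np.ndarray:
    out = arr[:, : arr.shape[1] - w + 1].copy()
    for off in range(1, w):
        out |= arr[:, off : arr.shape[1] - w + 1 + off]
    return out


def window_contingency(
    reads: list[ReadRecord],
    length: int,
    window: int = WINDOW,
    mode: str = "dms",
) -> list[WindowPair]:
    """Exact 2x2 contingency counts for every ordered window pair.

    A window (start position i, 1-based) counts as covered in a read iff
    all ``window`` positions are valid after signature filtering, and as
    modified iff at least one retained mutation falls inside it.  All
    pairs with non-overlapping windows (j >= i + window) are returned.
    """
    if length < 2 * window:
        raise ValueError(f"target length {length} < two windows of {window}")
    mut, valid = _read_matrices(reads, length, mode)
    cov = _sliding_all(valid, window)
    mod = _sliding_any(mut, window) & cov
    covf = cov.astype(np.float32)
    modf = mod.astype(np.float32)
    n_cov = covf.T @ covf  # reads covering both windows
    n_mm = modf.T @ modf  # modified in both
    n_mc = modf.T @ covf  # modified in first, covered in second

    pairs: list[WindowPair] = []
    n_win = length - window + 1
    for a in range(n_win):
        for b in range(a + window, n_win):
            n11 = int(round(n_mm[a, b]))
            n10 = int(round(n_mc[a, b])) - n11
            n01 = int(round(n_mc[b, a])) - n11
            n00 = int(round(n_cov[a, b])) - n11 - n10 - n01
            pairs.append(WindowPair(a + 1, b + 1, n11, n10, n01, n00))
    return pairs


def g_statistic(n11: int, n10: int, n01: int, n00: int) -> float:
    """Likelihood-ratio (G) test statistic of independence for a 2x2 table.

    G = 2 sum O ln(O/E) with expectations from the margins; zero cells
    contribute nothing, and a table with a zero margin has G = 0.
    """
    obs = np.array([[n11, n10], [n01, n00]], dtype=float)
    total = obs.sum()
    if total == 0:
        return 0.0
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        return 0.0
    exp = row * col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = special.xlogy(obs, obs / exp)
    return float(2.0 * terms.sum())


def _complementary(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def _window_complementarity(seq: str, i: int, j: int, window: int = WINDOW) -> int:
    """Number of antiparallel-register complementary positions (WC or GU)."""
    return sum(
        _complementary(seq[i - 1 + k], seq[j - 1 + window - 1 - k])
        for k in range(window)
    )


def pair_correlations(
    pairs: list[WindowPair],
    profile: ReactivityProfile,
    alpha: float = 0.05,
    min_comod: int = MIN_COMOD,
    window: int = WINDOW,
) -> list[WindowPair]:
    """Test and classify window pairs into principal / minor / rejected.

    Pipeline per pair: (1) require the windows to be separated by at
    least a minimal hairpin loop (a closer "duplex" is sterically
    impossible); (2) require n11 >= ``min_comod`` co-modifications;
    (3) require positive association (observed n11 above its independence
    expectation); (4) G-test of independence (df = 1), Bonferroni-corrected
    over all pairs passing (1)-(3), significant at ``alpha``; (5) require
    all 3 antiparallel window positions complementary (WC/GU); (6) both
    windows fully unmasked with mean normalized reactivity >= 0.2 (minor);
    principal additionally needs mean reactivity >= 0.4 and each window's
    partner to be its highest-G significant partner (mutual best).
    """
    if profile.reactivity is None:
        raise ValueError("profile has no normalized reactivities")
    seq = profile.sequence
    react = profile.reactivity
    mask = profile.mask

    tested: list[WindowPair] = []
    for p in pairs:
        if p.j < p.i + window + MIN_LOOP:
            p.pair_class, p.reason = PairClass.REJECTED, "too_close"
            continue
        if p.n11 < min_comod:
            p.pair_class, p.reason = PairClass.REJECTED, "comod_below_cutoff"
            continue
        exp11 = (p.n11 + p.n10) * (p.n11 + p.n01) / max(p.depth, 1)
        if p.n11 <= exp11:
            p.pair_class, p.reason = PairClass.REJECTED, "not_positively_associated"
            continue
        p.g_stat = g_statistic(p.n11, p.n10, p.n01, p.n00)
        tested.append(p)

    n_tests = len(tested)
    significant: list[WindowPair] = []
    for p in tested:
        p_raw = float(stats.chi2.sf(p.g_stat, df=1))
        p.p_corrected = min(1.0, p_raw * n_tests)
        if p.p_corrected > alpha:
            p.pair_class, p.reason = PairClass.REJECTED, "not_significant"
            continue
        if _window_complementarity(seq, p.i, p.j, window) < MIN_COMPLEMENTARY:
            p.pair_class, p.reason = PairClass.REJECTED, "not_complementary"
            continue
        wi = slice(p.i - 1, p.i - 1 + window)
        wj = slice(p.j - 1, p.j - 1 + window)
        if not (mask[wi].all() and mask[wj].all()):
            p.pair_class, p.reason = PairClass.REJECTED, "window_masked"
            continue
        significant.append(p)

    # mean window reactivity gates + mutual-best for principal
    best_partner: dict[int, tuple[float, int]] = {}
    for p in significant:
        for w, other in ((p.i, p.j), (p.j, p.i)):
            if w not in best_partner or p.g_stat > best_partner[w][0]:
                best_partner[w] = (p.g_stat, other)
    for p in significant:
        wi = slice(p.i - 1, p.i - 1 + window)
        wj = slice(p.j - 1, p.j - 1 + window)
        mean_react = min(float(react[wi].mean()), float(react[wj].mean()))
        if mean_react < MINOR_REACTIVITY:
            p.pair_class, p.reason = PairClass.REJECTED, "low_reactivity"
        elif (
            mean_react >= PRINCIPAL_REACTIVITY
            and best_partner[p.i][1] == p.j
            and best_partner[p.j][1] == p.i
        ):
            p.pair_class, p.reason = PairClass.PRINCIPAL, ""
        else:
            p.pair_class, p.reason = PairClass.MINOR, ""
    return pairs


def _helices(structure: ReferenceStructure, min_len: int = 3) -> list[list[tuple[int, int]]]:
    """Maximal stacks of consecutive pairs with at least ``min_len`` bp."""
    pairs = set(structure.pairs())
    helices = []
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pairs:
            continue  # not a helix 5' end
        helix = [(i, j)]
        while (helix[-1][0] + 1, helix[-1][1] - 1) in pairs:
            helix.append((helix[-1][0] + 1, helix[-1][1] - 1))
        if len(helix) >= min_len:
            helices.append(helix)
    return helices


def _pair_matches_structure(
    p: WindowPair,
    pairs: set[tuple[int, int]],
    window: int = WINDOW,
    allow_shift: bool = True,
) -> bool:
    """True if any of the window's antiparallel base pairs is in the
    structure, allowing a one-position register shift."""
    for k in range(window):
        i, j = p.i + k, p.j + window - 1 - k
        cands = [(i, j)]
        if allow_shift:
            cands += [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
        for a, b in cands:
            if a < b and (a, b) in pairs:
                return True
    return False


def pair_ppv_sens(
    pairs: list[WindowPair],
    structure: ReferenceStructure,
    mask: np.ndarray | None = None,
    window: int = WINDOW,
) -> tuple[float, float]:
    """ppv/sens of reported PAIRs against an accepted structure.

    A PAIR (principal or minor) is correct if its windows overlap a true
    duplex in antiparallel register (any of the 3 window base pairs
    present, one-position shift allowed).  sens = fraction of accepted
    helices (>= 3 bp, all positions data-covered when a mask is given)
    hit by at least one correct PAIR; ppv = fraction of reported PAIRs
    that are correct (NaN when none are reported).
    """
    truth = set(structure.pairs())
    truth |= {(j, i) for i, j in truth}
    reported = [p for p in pairs if p.pair_class is not PairClass.REJECTED]
    correct = [p for p in reported if _pair_matches_structure(p, truth, window)]
    ppv = len(correct) / len(reported) if reported else math.nan

    helices = _helices(structure)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        helices = [
            h for h in helices
            if all(mask[i - 1] and mask[j - 1] for i, j in h)
        ]
    n_hit = 0
    for helix in helices:
        hp = set(helix) | {(j, i) for i, j in helix}
        if any(_pair_matches_structure(p, hp, window) for p in correct):
            n_hit += 1
    sens = n_hit / len(helices) if helices else math.nan
    return ppv, sens


def write_pair_tsv(pairs: list[WindowPair], path: str, all_pairs: bool = False) -> None:
    """Write classified PAIRs as TSV (i, j, n11, depth, g_stat,
    corrected_p, class); rejected pairs included only with ``all_pairs``."""
    rows = [
        dict(
            i=p.i, j=p.j, n11=p.n11, depth=p.depth,
            g_stat=round(p.g_stat, 4), corrected_p=p.p_corrected,
            pair_class=p.pair_class.value, reason=p.reason,
        )
        for p in pairs
        if all_pairs or p.pair_class is not PairClass.REJECTED
    ]
    pd.DataFrame(
        rows,
        columns=["i", "j", "n11", "depth", "g_stat", "corrected_p", "pair_class", "reason"],
    ).to_csv(path, sep="\t", index=False)
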