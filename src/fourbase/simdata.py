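"""Synthetic four-base DMS-MaP read generator with full ground truth.

The generator emulates the chemistry the pipeline assumes, per molecule:

1. draw a conformational state from a (possibly multi-state) ensemble of
   secondary structures;
2. at each position, draw Watson-Crick-face adducts as Bernoulli events
   conditioned on pairing status in that state (defaults: unpaired A/C
   0.02, U 0.006, N1-G 0.001; paired rates 10-fold lower), plus N7-G
   adducts at every G regardless of pairing (default rate 0.5);
3. detect each adduct with a class-specific efficiency (N7-G is read
   through only ~2% of the time) and emit its mutational signature
   (N1-G → G→C/G→T, N7-G → G→A, A/C/U → a random mismatch);
4. superimpose background errors: random substitutions (rate 0.001) and
   indels (rate 0.002, split evenly between deletions and insertions).

Two-state ensembles with a melted helix produce the correlated
co-modification that PAIR analysis detects.  Every emitted event is
traceable to its cause through :class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mutation_data import MutationEvent, ReadRecord
from .structure_io import ReferenceStructure

__all__ = [
    "SimParams",
    "SimTruth",
    "CAUSE_CODES",
    "simulate_reads",
    "planted_helix_ensemble",
    "untreated_params",
    "default_toy_structure",
]

# cause codes in SimTruth.cause
CAUSE_CODES = {
    0: "none",
    1: "n1_adduct",  # Watson-Crick-face adduct at A/C/U or N1-G
    2: "n7g_adduct",
    3: "bg_substitution",
    4: "bg_indel",
}

DEFAULT_UNPAIRED_RATES = {"A": 0.02, "C": 0.02, "U": 0.006, "G": 0.001}
PAIRED_RATE_RATIO = 0.1  # paired rates are 10-fold lower (configurable default)
# N7-G methylation varies by position within an estimated 0.2-0.8 range,
# independent of pairing; that heterogeneity is what buries the G signal
DEFAULT_N7G_RATE = (0.2, 0.8)
DEFAULT_N7G_DETECT = 0.02  # N7-G adducts read through at 1-3%
DEFAULT_BG_SUB = 0.001
DEFAULT_BG_INDEL = 0.002


@dataclass
class SimParams:
    """Generative parameters for one simulated probing experiment.

    ``structures`` with ``weights`` define the conformational ensemble;
    adduct rates are per-molecule Bernoulli probabilities, split by
    pairing status; signatures are multinomials over emitted mutation
    types.  N1-G detection is folded into its adduct rate (the ~0.001
    default is the effective detected rate); N7-G keeps an explicit
    detection efficiency because its adduct rate (~0.5) and read-through
    (~0.02) are separately meaningful.
    """

    structures: list[ReferenceStructure]
    weights: np.ndarray = None
    unpaired_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNPAIRED_RATES)
    )
    paired_rates: dict[str, float] = None
    n7g_rate: float | tuple[float, float] = DEFAULT_N7G_RATE
    n7g_detect: float = DEFAULT_N7G_DETECT
    n1g_signature: dict[str, float] = field(
        default_factory=lambda: {"C": 0.5, "U": 0.5}
    )
    n7g_signature: dict[str, float] = field(default_factory=lambda: {"A": 1.0})
    bg_sub_rate: float = DEFAULT_BG_SUB
    bg_indel_rate: float = DEFAULT_BG_INDEL

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("at least one structure required")
        n = len(self.structures[0])
        if any(len(s) != n for s in self.structures):
            raise ValueError("all ensemble structures must share one length")
        if self.weights is None:
            self.weights = np.full(len(self.structures), 1.0 / len(self.structures))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.structures):
            raise ValueError("one weight per structure required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError(f"ensemble weights sum to {self.weights.sum()}, not 1")
        if self.paired_rates is None:
            self.paired_rates = {
                b: r * PAIRED_RATE_RATIO for b, r in self.unpaired_rates.items()
            }
        n7 = self.n7g_rate if isinstance(self.n7g_rate, tuple) else (self.n7g_rate,)
        for name, probs in [
            ("unpaired_rates", self.unpaired_rates.values()),
            ("paired_rates", self.paired_rates.values()),
            ("rates", [*n7, self.n7g_detect, self.bg_sub_rate, self.bg_indel_rate]),
        ]:
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
        for name, sig in [("n1g_signature", self.n1g_signature),
                          ("n7g_signature", self.n7g_signature)]:
            if sig and not np.isclose(sum(sig.values()), 1.0):
                raise ValueError(f"{name} multinomial must sum to 1")

    @property
    def sequence(self) -> str:
        return self.structures[0].sequence


@dataclass
class SimTruth:
    """Ground truth for a simulated read set.

    ``state[m]`` is molecule m's ensemble state index; ``cause[m, p]``
    codes the origin of the event emitted at position p+1 of read m
    (see :data:`CAUSE_CODES`; 0 = no event).  ``adducts[c]`` are the raw
    (pre-detection) adduct indicator matrices per class, and
    ``n7g_site_rate`` the realized per-position N7-G modification rates.
    """

    state: np.ndarray
    cause: np.ndarray
    adducts: dict[str, np.ndarray]
    n7g_site_rate: np.ndarray | None = None

    def events_by_cause(self, code: int) -> int:
        return int((self.cause == code).sum())


def _mismatch_base(rng: np.random.Generator, ref: str, n: int) -> np.ndarray:
    """Uniformly random substitute bases (excluding the reference base)."""
    others = np.array([b for b in "ACGU" if b != ref])
    return others[rng.integers(0, 3, size=n)]


def simulate_reads(
    params: SimParams, n_reads: int, seed: int | None = None
) -> tuple[list[ReadRecord], SimTruth]:
    """Simulate full-length reads and their ground truth.

    Molecules are full length; at most one event is emitted per position
    per read, with adduct signatures taking precedence over background
    errors (and N1 over N7 at a doubly modified G) so that every event
    has exactly one cause.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    seq = params.sequence
    length = len(seq)
    base_arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    is_g = base_arr == "G"

    paired_by_state = np.stack([s.is_paired() for s in params.structures])
    state = rng.choice(len(params.structures), size=n_reads, p=params.weights)
    paired = paired_by_state[state]  # (n_reads, length)

    rate_paired = np.array([params.paired_rates.get(b, 0.0) for b in base_arr])
    rate_unpaired = np.array([params.unpaired_rates.get(b, 0.0) for b in base_arr])
    rate = np.where(paired, rate_paired, rate_unpaired)

    u = rng.random((n_reads, length))
    n1_adduct = u < rate
    # per-position N7-G rate: constant, or drawn once per site from the
    # configured range (positional heterogeneity independent of pairing)
    n7g_site = np.zeros(length)
    if isinstance(params.n7g_rate, tuple):
        lo_r, hi_r = params.n7g_rate
        n7g_site[is_g] = rng.uniform(lo_r, hi_r, size=int(is_g.sum()))
    else:
        n7g_site[is_g] = params.n7g_rate
    n7_adduct = rng.random((n_reads, length)) < n7g_site
    n7_detected = n7_adduct & (rng.random((n_reads, length)) < params.n7g_detect)

    bg_sub = rng.random((n_reads, length)) < params.bg_sub_rate
    bg_indel = rng.random((n_reads, length)) < params.bg_indel_rate

    # precedence: N1-class adduct > N7-G > background substitution > indel
    cause = np.zeros((n_reads, length), dtype=np.int8)
    cause[bg_indel] = 4
    cause[bg_sub] = 3
    cause[n7_detected] = 2
    cause[n1_adduct] = 1

    rows, cols = np.nonzero(cause)
    n_ev = len(rows)
    ref_all = base_arr[cols]
    c_all = cause[rows, cols]

    # draw every event's emitted base in one vectorized pass per cause class
    alt_all = np.empty(n_ev, dtype="U1")
    sel = (c_all == 1) & (ref_all == "G")
    if sel.any():
        bases = np.array(list(params.n1g_signature))
        probs = np.array(list(params.n1g_signature.values()))
        alt_all[sel] = rng.choice(bases, size=int(sel.sum()), p=probs)
    sel = c_all == 2
    if sel.any():
        bases = np.array(list(params.n7g_signature))
        probs = np.array(list(params.n7g_signature.values()))
        alt_all[sel] = rng.choice(bases, size=int(sel.sum()), p=probs)
    for ref in "ACGU":
        sel = (ref_all == ref) & (
            (c_all == 3) | ((c_all == 1) & (ref_all != "G"))
        )
        if sel.any():
            alt_all[sel] = _mismatch_base(rng, ref, int(sel.sum()))
    indel_sel = c_all == 4
    is_deletion = rng.random(n_ev) < 0.5
    ins_base = np.array(list("ACGU"))[rng.integers(0, 4, size=n_ev)]

    reads: list[ReadRecord] = []
    # rows from nonzero are sorted; group event indices by read
    boundaries = np.searchsorted(rows, np.arange(n_reads + 1))
    for m in range(n_reads):
        events = []
        for e in range(boundaries[m], boundaries[m + 1]):
            p = int(cols[e]) + 1
            if indel_sel[e]:
                if is_deletion[e]:
                    events.append(MutationEvent(p, p, str(ref_all[e]), ""))
                else:
                    events.append(MutationEvent(p, p, "", str(ins_base[e])))
            else:
                events.append(MutationEvent(p, p, str(ref_all[e]), str(alt_all[e])))
        reads.append(ReadRecord(f"read_{m}", 1, length, events))

    truth = SimTruth(
        state=state,
        cause=cause,
        adducts={"n1": n1_adduct, "n7g": n7_adduct},
        n7g_site_rate=n7g_site,
    )
    return reads, truth


def planted_helix_ensemble(
    base_structure: ReferenceStructure,
    helix: list[tuple[int, int]],
    open_fraction: float,
    **kwargs,
) -> SimParams:
    """Two-state ensemble in which a helix is melted in a fraction of
    molecules, generating correlated co-modification across its strands.

    State 1 is the base structure (helix formed, weight 1 − f); state 2
    has the helix pairs removed (both strands unpaired, weight f).
    """
    if not 0 < open_fraction < 1:
        raise ValueError("open_fraction must lie strictly between 0 and 1")
    melted = base_structure.melt(helix)
    return SimParams(
        structures=[base_structure, melted],
        weights=np.array([1.0 - open_fraction, open_fraction]),
        **kwargs,
    )


def untreated_params(params: SimParams) -> SimParams:
    """The matched untreated control: same generator, all adduct rates 0."""
    zero = {b: 0.0 for b in params.unpaired_rates}
    return replace(
        params,
        unpaired_rates=zero,
        paired_rates=dict(zero),
        n7g_rate=0.0,
    )


TOY_DB = (
    "...((((((((......))))))))...........((((((((....))))))))...."
    "....................((((((((......))))))))....((((((....)))"
    ")))......((((......))))......."
)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def structure_from_dotbracket(
    db: str, name: str = "synthetic", seed: int = 20
) -> ReferenceStructure:
    """Build a synthetic RNA whose sequence realizes a dot-bracket shape.

    Paired positions get Watson-Crick-complementary bases; unpaired
    positions cycle deterministically (seeded) through all four bases, so
    helices are canonical and loops are mixed-composition.
    """
    from .structure_io import parse_dotbracket

    skeleton = parse_dotbracket(db, name=name)
    rng = np.random.default_rng(seed)
    seq = [""] * len(skeleton)
    for i, j in enumerate(skeleton.pair_table, start=1):
        if seq[i - 1]:
            continue
        base = "ACGU"[rng.integers(0, 4)]
        seq[i - 1] = base
        if j > i:
            seq[j - 1] = _COMPLEMENT[base]
    return ReferenceStructure(name, "".join(seq), skeleton.pair_table)


def default_toy_structure() -> ReferenceStructure:
    """A 150-nt toy RNA with several helices, used across tests and docs."""
    return structure_from_dotbracket(TOY_DB, name="toy150")
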