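"""Reference secondary structures: parsing, writing and accuracy scoring.

Structures are held as a 1-based pair table (CT convention): entry ``i``
gives the partner of position ``i+1``, with 0 meaning unpaired.  Crossing
(pseudoknotted) pairs are first-class — dot-bracket input may use up to
four bracket tiers ``() [] {} <>`` and round-trips losslessly.

Predicted structures are scored against accepted references with the
ppv/sens conventions standard in chemical-probing work: only canonical
Watson-Crick and GU pairs are counted, singleton (unstacked) pairs are
dropped, and a predicted pair may match an accepted pair shifted by one
position on either strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceStructure",
    "StructureError",
    "parse_dotbracket",
    "parse_ct",
    "write_ct",
    "write_dotbracket",
    "read_structure_file",
    "compare_structures",
]

BRACKET_TIERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
_OPEN = {o: k for k, (o, _) in enumerate(BRACKET_TIERS)}
_CLOSE = {c: k for k, (_, c) in enumerate(BRACKET_TIERS)}

CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


class StructureError(ValueError):
    """Malformed structure text or inconsistent pair table."""


@dataclass
class ReferenceStructure:
    """An RNA sequence plus a symmetric, possibly pseudoknotted pair table.

    Attributes
    ----------
    name : str
        Free-text label.
    sequence : str
        Uppercase RNA alphabet {A, C, G, U, N}; DNA T is normalized to U.
    pair_table : numpy.ndarray of int
        ``pair_table[i]`` is the 1-based partner of position ``i+1``;
        0 marks an unpaired position.
    """

    name: str
    sequence: str
    pair_table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        self.pair_table = np.asarray(self.pair_table, dtype=int)
        if len(self.sequence) != len(self.pair_table):
            raise StructureError(
                f"sequence length {len(self.sequence)} != pair table length "
                f"{len(self.pair_table)}"
            )
        self._validate()

    def _validate(self) -> None:
        n = len(self.pair_table)
        for i, j in enumerate(self.pair_table, start=1):
            if j == 0:
                continue
            if not 1 <= j <= n:
                raise StructureError(f"position {i}: partner {j} out of range")
            if j == i:
                raise StructureError(f"position {i} pairs with itself")
            if self.pair_table[j - 1] != i:
                raise StructureError(
                    f"asymmetric pair table: {i}->{j} but {j}->{self.pair_table[j - 1]}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def pairs(self) -> list[tuple[int, int]]:
        """All base pairs as 1-based (i, j) with i < j, sorted by i."""
        return [
            (i, int(j))
            for i, j in enumerate(self.pair_table, start=1)
            if j > i
        ]

    def is_paired(self) -> np.ndarray:
        """Boolean array: True where the position is base-paired."""
        return self.pair_table > 0

    def melt(self, pairs: list[tuple[int, int]], name: str | None = None) -> "ReferenceStructure":
        """Return a copy with the given pairs removed (both partners unpaired)."""
        table = self.pair_table.copy()
        for i, j in pairs:
            if table[i - 1] != j:
                raise StructureError(f"pair ({i},{j}) not present; cannot melt")
            table[i - 1] = 0
            table[j - 1] = 0
        return ReferenceStructure(name or f"{self.name}:melted", self.sequence, table)


def normalize_sequence(seq: str) -> str:
    seq = seq.strip().upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise StructureError(f"unexpected sequence characters: {sorted(bad)}")
    return seq


def parse_dotbracket(text: str, sequence: str | None = None, name: str = "") -> ReferenceStructure:
    """Parse dot-bracket notation (tiers ``() [] {} <>``) into a structure.

    ``text`` may be a bare bracket string or a small file body with an
    optional ``>name`` header line followed by a sequence line and the
    bracket line.
    """
    seq = sequence
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty dot-bracket input")
    if lines[0].startswith(">"):
        name = name or lines[0][1:].strip()
        lines = lines[1:]
    if len(lines) == 1:
        db = lines[0]
    elif len(lines) == 2:
        seq = seq or lines[0]
        db = lines[1]
    else:
        raise StructureError("expected at most [>name], [sequence], structure lines")

    n = len(db)
    if n == 0:
        raise StructureError("empty structure string")
    if seq is None:
        seq = "N" * n
    if len(seq) != n:
        raise StructureError(f"sequence length {len(seq)} != structure length {n}")

    table = np.zeros(n, dtype=int)
    stacks: list[list[int]] = [[] for _ in BRACKET_TIERS]
    for pos, ch in enumerate(db, start=1):
        if ch in ".-":
            continue
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(pos)
        elif ch in _CLOSE:
            tier = _CLOSE[ch]
            if not stacks[tier]:
                raise StructureError(f"unbalanced '{ch}' at position {pos}")
            i = stacks[tier].pop()
            table[i - 1] = pos
            table[pos - 1] = i
        else:
            raise StructureError(f"unknown character '{ch}' at position {pos}")
    for tier, stack in enumerate(stacks):
        if stack:
            o = BRACKET_TIERS[tier][0]
            raise StructureError(f"unbalanced '{o}' opened at position {stack[-1]}")
    return ReferenceStructure(name, seq, table)


def parse_ct(text: str) -> ReferenceStructure:
    """Parse a single standard 6-column CT record."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty CT input")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise StructureError(f"bad CT header line: {lines[0]!r}") from exc
    name = " ".join(header[1:])
    body = lines[1:]
    if len(body) != n:
        raise StructureError(f"CT header declares {n} positions, found {len(body)}")
    seq = []
    table = np.zeros(n, dtype=int)
    for ln in body:
        cols = ln.split()
        if len(cols) < 6:
            raise StructureError(f"CT line has {len(cols)} columns, need 6: {ln!r}")
        idx = int(cols[0])
        if not 1 <= idx <= n:
            raise StructureError(f"CT index {idx} out of range 1..{n}")
        seq.append(cols[1])
        table[idx - 1] = int(cols[4])
    # ReferenceStructure.__post_init__ enforces symmetry
    return ReferenceStructure(name, "".join(seq), table)


def write_ct(struct: ReferenceStructure) -> str:
    """Render a structure as a standard 6-column CT record."""
    n = len(struct)
    out = [f"{n} {struct.name}".rstrip()]
    for i in range(1, n + 1):
        out.append(
            f"{i:>5} {struct.sequence[i - 1]} {i - 1:>5} "
            f"{(i + 1) if i < n else 0:>5} {struct.pair_table[i - 1]:>5} {i:>5}"
        )
    return "\n".join(out) + "\n"


def write_dotbracket(struct: ReferenceStructure) -> str:
    """Render as dot-bracket, assigning crossing pairs to higher tiers.

    Raises if more than four mutually crossing tiers are required.
    """
    chars = ["."] * len(struct)
    tiers: list[list[tuple[int, int]]] = [[] for _ in BRACKET_TIERS]
    for i, j in struct.pairs():
        for k, placed in enumerate(tiers):
            if all(not _crossing((i, j), p) for p in placed):
                placed.append((i, j))
                o, c = BRACKET_TIERS[k]
                chars[i - 1], chars[j - 1] = o, c
                break
        else:
            raise StructureError("structure needs more than 4 bracket tiers")
    header = f">{struct.name}\n" if struct.name else ""
    return f"{header}{struct.sequence}\n{''.join(chars)}\n"


def _crossing(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def read_structure_file(path: str) -> ReferenceStructure:
    """Load a structure from a .ct or dot-bracket file (sniffed by content)."""
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines and not lines[0].startswith(">"):
        head = lines[0].split()
        if head and head[0].isdigit() and len(lines) > 1 and len(lines[1].split()) >= 6:
            return parse_ct(text)
    return parse_dotbracket(text)


# ---------------------------------------------------------------------------
# ppv / sens scoring


def _canonical_pairs(struct: ReferenceStructure) -> set[tuple[int, int]]:
    seq = struct.sequence
    return {
        (i, j)
        for i, j in struct.pairs()
        if (seq[i - 1], seq[j - 1]) in CANONICAL_PAIRS
    }


def _drop_singletons(pairs: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Remove pairs with no stacked neighbour (i-1,j+1) or (i+1,j-1)."""
    return {
        (i, j)
        for i, j in pairs
        if (i - 1, j + 1) in pairs or (i + 1, j - 1) in pairs
    }


def _shift_neighborhood(pair: tuple[int, int], allow_shift: bool):
    i, j = pair
    yield (i, j)
    if allow_shift:
        for cand in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if cand[0] < cand[1]:
                yield cand


def compare_structures(
    predicted: ReferenceStructure,
    accepted: ReferenceStructure,
    allow_shift: bool = True,
    ignore_singletons: bool = True,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Score a predicted structure against an accepted reference.

    Returns ``(ppv, sens)``: ppv = TP / predicted pairs, sens = TP /
    accepted pairs, counting only canonical WC/GU pairs.  A predicted pair
    is a true positive if it matches an accepted pair exactly or (with
    ``allow_shift``) shifted by one position on either strand; each
    accepted pair can be claimed at most once (one-to-one assignment,
    5'-first tie-break).  Pairs
    touching a position where ``mask`` is False (no data) are excluded
    from both counts.  ppv with zero predicted pairs is NaN.
    """
    if len(predicted) != len(accepted):
        raise StructureError(
            f"length mismatch: predicted {len(predicted)} vs accepted {len(accepted)}"
        )
    pred = _canonical_pairs(predicted)
    acc = _canonical_pairs(accepted)
    if ignore_singletons:
        pred = _drop_singletons(pred)
        acc = _drop_singletons(acc)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        pred = {(i, j) for i, j in pred if mask[i - 1] and mask[j - 1]}
        acc = {(i, j) for i, j in acc if mask[i - 1] and mask[j - 1]}

    # one-to-one assignment of predicted to accepted pairs (maximum
    # bipartite matching; greedy 5'-first claiming alone can strand a
    # predicted pair whose only partner was taken by a shifted neighbour)
    candidates = {
        p: [c for c in _shift_neighborhood(p, allow_shift) if c in acc]
        for p in sorted(pred)
    }
    owner: dict[tuple[int, int], tuple[int, int]] = {}

    def try_assign(p, seen):
        for c in candidates[p]:
            if c in seen:
                continue
            seen.add(c)
            if c not in owner or try_assign(owner[c], seen):
                owner[c] = p
                return True
        return False

    for p in sorted(pred):
        try_assign(p, set())
    tp = len(owner)
    ppv = tp / len(pred) if pred else math.nan
    sens = tp / len(acc) if acc else math.nan
    return ppv, sens
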