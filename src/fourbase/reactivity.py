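"""Background-subtracted modification rates and nucleotide-specific
normalized DMS reactivities.

DMS modification rates differ by an order of magnitude between nucleotide
types (A/C ≫ U ≫ N1-G), so reactivities are normalized per type.  The
normalization factor for type n is

    N_n = max{ mean of rates within the [P90, P95] band,
               P75 of rates > 0.001 }

(the second term makes the scheme robust for molecules where most
nucleotides are unreactive, e.g. rRNA).  Normalized reactivity is the
background-subtracted modification rate divided by N_n, giving a common
~0-1 scale across all four bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mutation_data import PositionCounts
from .structure_io import normalize_sequence

__all__ = [
    "ReactivityProfile",
    "NormalizationError",
    "modification_rate",
    "normalization_factor",
    "normalize",
    "write_dms",
    "read_dms",
]

NO_DATA_SENTINEL = -999.0
MIN_VALUES_FOR_NORM = 10
RATE_FLOOR = 0.001  # the ">0.001" subset in the second normalization term


class NormalizationError(ValueError):
    """Raised when a normalization factor cannot be computed."""


@dataclass
class ReactivityProfile:
    """Per-position reactivity state for one RNA.

    ``mod_rate`` is the background-subtracted DMS modification rate
    (treated − untreated, or treated alone without a control); negative
    values are retained, not clamped.  ``mask`` is False at no-data
    positions (low depth, high background, filtered out).  After
    :func:`normalize`, ``reactivity[i] = mod_rate[i] / norm_factor[base]``
    wherever ``mask`` is True.
    """

    sequence: str
    modified_rate: np.ndarray
    untreated_rate: np.ndarray | None = None
    mod_rate: np.ndarray | None = None
    norm_factor: dict[str, float] = field(default_factory=dict)
    reactivity: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        n = len(self.sequence)
        for name in ("modified_rate", "untreated_rate", "mod_rate", "reactivity"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != n:
                    raise ValueError(f"{name} length {len(arr)} != sequence length {n}")
                setattr(self, name, arr)
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.sequence)

    def base_array(self) -> np.ndarray:
        return np.frombuffer(self.sequence.encode(), dtype="S1").astype("U1")


def modification_rate(
    treated: PositionCounts,
    untreated: PositionCounts | None = None,
    min_depth: int = 1000,
    max_background: float = 0.05,
) -> ReactivityProfile:
    """Compute background-subtracted per-position modification rates.

    ``mod_rate = treated_rate − untreated_rate`` when a control is given,
    else the treated rate alone.  QC masking: positions with effective
    depth below ``min_depth`` in either sample, or untreated rate above
    ``max_background``, are marked no-data.  Negative subtracted rates
    are retained and simply flagged via a warning.
    """
    n = len(treated)
    t_rate = treated.rate()
    mask = treated.effective_depth >= min_depth
    u_rate = None
    if untreated is not None:
        if len(untreated) != n:
            raise ValueError("treated/untreated length mismatch")
        u_rate = untreated.rate()
        mask &= untreated.effective_depth >= min_depth
        with np.errstate(invalid="ignore"):
            mask &= ~(u_rate > max_background)
        mod = t_rate - u_rate
    else:
        mod = t_rate.copy()
    mask &= np.isfinite(mod)
    mod = np.where(np.isfinite(mod), mod, 0.0)
    n_neg = int((mod[mask] < 0).sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} positions have negative background-subtracted rates "
            "(retained, not clamped)",
            stacklevel=2,
        )
    return ReactivityProfile(
        treated.sequence,
        modified_rate=t_rate,
        untreated_rate=u_rate,
        mod_rate=mod,
        mask=mask,
    )


def normalization_factor(values: np.ndarray) -> float:
    """Normalization factor N_n for one nucleotide type.

    ``N_n = max(term1, term2)`` with term1 the mean of values inside the
    interpolated [P90, P95] percentile band (fallback: interpolated 92.5th
    percentile when the band is empty) and term2 the 75th percentile of
    the subset of values > 0.001; when that subset is empty, N_n = term1.
    Percentiles use linear interpolation throughout.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < MIN_VALUES_FOR_NORM:
        raise NormalizationError(
            f"need >= {MIN_VALUES_FOR_NORM} values, got {len(values)}"
        )
    if not (values > 0).any():
        raise NormalizationError("all modification rates are <= 0")
    p90, p95 = np.percentile(values, [90.0, 95.0])
    band = values[(values >= p90) & (values <= p95)]
    term1 = float(band.mean()) if len(band) else float(np.percentile(values, 92.5))
    above = values[values > RATE_FLOOR]
    if len(above) == 0:
        return term1
    term2 = float(np.percentile(above, 75.0))
    return max(term1, term2)


def normalize(profile: ReactivityProfile) -> ReactivityProfile:
    """Populate per-base normalization factors and normalized reactivities.

    Factors are computed per nucleotide type from the profile's own
    unmasked ``mod_rate`` values.  A type for which no factor is
    computable has all its positions masked (with a warning).  Masked
    positions get the no-data sentinel in ``reactivity``.
    """
    if profile.mod_rate is None:
        raise ValueError("profile has no mod_rate; run modification_rate first")
    bases = profile.base_array()
    mask = profile.mask.copy()
    factors: dict[str, float] = {}
    for base in "ACGU":
        sel = (bases == base) & mask
        if not sel.any():
            continue
        try:
            factors[base] = normalization_factor(profile.mod_rate[sel])
        except NormalizationError as exc:
            warnings.warn(f"no normalization factor for {base}: {exc}", stacklevel=2)
            mask[bases == base] = False
    reactivity = np.full(len(profile), NO_DATA_SENTINEL)
    for base, factor in factors.items():
        sel = (bases == base) & mask
        reactivity[sel] = profile.mod_rate[sel] / factor
    return ReactivityProfile(
        profile.sequence,
        modified_rate=profile.modified_rate,
        untreated_rate=profile.untreated_rate,
        mod_rate=profile.mod_rate,
        norm_factor=factors,
        reactivity=reactivity,
        mask=mask,
    )


def write_dms(profile: ReactivityProfile, path: str) -> None:
    """Write a normalized profile as a .dms text file.

    Whitespace-delimited columns: 1-based position, nucleotide, normalized
    reactivity; no-data positions carry the sentinel -999.
    """
    if profile.reactivity is None:
        raise ValueError("profile not normalized; nothing to write")
    with open(path, "w") as fh:
        for i, base in enumerate(profile.sequence):
            val = profile.reactivity[i] if profile.mask[i] else NO_DATA_SENTINEL
            fh.write(f"{i + 1}\t{base}\t{val:.6f}\n")


def read_dms(path: str) -> ReactivityProfile:
    """Read a .dms file back into a (normalized-only) profile."""
    positions, bases, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            pos, base, val = line.split()
            positions.append(int(pos))
            bases.append(base)
            vals.append(float(val))
    if positions != list(range(1, len(positions) + 1)):
        raise ValueError(f"{path}: positions are not contiguous from 1")
    reactivity = np.array(vals)
    mask = reactivity != NO_DATA_SENTINEL
    seq = "".join(bases)
    return ReactivityProfile(
        seq,
        modified_rate=np.full(len(seq), np.nan),
        reactivity=reactivity,
        mask=mask,
    )
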