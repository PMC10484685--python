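"""Information metrics for chemical-probing data.

Three layers:

* ``auroc`` — how well reactivity separates unpaired from paired positions
  (unpaired is the positive class; Mann-Whitney rank convention for ties).

* ``GammaMixture`` / ``fit_gamma_mixture`` — the per-nucleotide-type
  reactivity likelihoods p̂(r|paired) and p̂(r|unpaired), each a
  two-component gamma mixture over positive reactivities plus a point
  mass at r ≤ 0 (normalized profiles contain zeros and negatives).

* ``structural_information`` / ``expected_structural_information`` — the
  per-position structural information in bits,

      SI(r) = 1 − H(s | r),   p(b|r) = p̂(r|b) / (p̂(r|b) + p̂(r|u)),

  i.e. the reduction in Shannon entropy of the two-state pairing status
  relative to the 0.5/0.5 no-data prior, and its average over the
  molecule (ESI).  ESI ranges from 0 (likelihoods identical, data carry
  no information) to 1 (disjoint likelihoods, pairing status perfectly
  specified at every position).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .reactivity import ReactivityProfile
from .structure_io import ReferenceStructure

__all__ = [
    "GammaMixture",
    "StructureModels",
    "ESIResult",
    "FitError",
    "auroc",
    "fit_gamma_mixture",
    "posterior_paired",
    "structural_information",
    "expected_structural_information",
]

DENSITY_FLOOR = 1e-12


def auroc(
    values: np.ndarray,
    is_unpaired: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Area under the ROC curve, unpaired = positive class.

    Computed from the Mann-Whitney U statistic, AUROC = U / (n1 * n0),
    which handles ties by the rank (half-credit) convention.  Returns NaN
    when only one class survives masking.
    """
    values = np.asarray(values, dtype=float)
    is_unpaired = np.asarray(is_unpaired, dtype=bool)
    keep = np.isfinite(values)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    v, y = values[keep], is_unpaired[keep]
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        return math.nan
    u = stats.mannwhitneyu(v[y], v[~y], alternative="two-sided").statistic
    return float(u) / (n1 * n0)


# ---------------------------------------------------------------------------
# double-gamma mixture with zero mass


class FitError(RuntimeError):
    """Mixture fit failed; carries the best parameters found so far."""

    def __init__(self, message: str, best: "GammaMixture | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class GammaMixture:
    """Two-component gamma mixture plus a point mass at r ≤ 0.

    ``weights`` (two entries) and ``zero_mass`` sum to 1; the continuous
    density over r > 0 integrates to ``1 − zero_mass``.
    """

    weights: np.ndarray
    shapes: np.ndarray
    scales: np.ndarray
    zero_mass: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        total = self.weights.sum() + self.zero_mass
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"weights + zero_mass = {total}, expected 1")
        if (self.shapes <= 0).any() or (self.scales <= 0).any():
            raise ValueError("shapes and scales must be positive")
        if (self.weights < 0).any() or not 0 <= self.zero_mass <= 1:
            raise ValueError("weights and zero_mass must be within [0, 1]")

    def pdf(self, r) -> np.ndarray:
        """Continuous mixture density at r (0 for r ≤ 0)."""
        scalar = np.ndim(r) == 0
        r = np.atleast_1d(np.asarray(r, dtype=float))
        out = np.zeros_like(r)
        pos = r > 0
        for w, k, s in zip(self.weights, self.shapes, self.scales):
            if w > 0:
                out[pos] += w * stats.gamma.pdf(r[pos], a=k, scale=s)
        return out[0] if scalar else out

    def likelihood(self, r) -> np.ndarray:
        """Mixed-measure likelihood: density for r > 0, zero_mass for r ≤ 0."""
        scalar = np.ndim(r) == 0
        r = np.atleast_1d(np.asarray(r, dtype=float))
        out = np.atleast_1d(self.pdf(r))
        out = np.where(r <= 0, self.zero_mass, out)
        return out[0] if scalar else out

    def mean(self) -> float:
        """Mean of the continuous part (conditional on r > 0)."""
        w = self.weights / self.weights.sum()
        return float(np.sum(w * self.shapes * self.scales))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n reactivities (zeros for the point-mass component)."""
        probs = np.append(self.weights, self.zero_mass)
        comp = rng.choice(3, size=n, p=probs / probs.sum())
        out = np.zeros(n)
        for k in (0, 1):
            sel = comp == k
            out[sel] = rng.gamma(self.shapes[k], self.scales[k], size=int(sel.sum()))
        return out

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "shapes": self.shapes.tolist(),
            "scales": self.scales.tolist(),
            "zero_mass": self.zero_mass,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GammaMixture":
        return cls(
            np.array(d["weights"]), np.array(d["shapes"]),
            np.array(d["scales"]), float(d["zero_mass"]),
        )


def _gamma_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE (shape, scale) via Newton on the digamma equation."""
    wsum = w.sum()
    m = float(np.dot(w, x) / wsum)
    mlog = float(np.dot(w, np.log(x)) / wsum)
    s = math.log(m) - mlog
    if s <= 0:  # numerically degenerate (near-constant data)
        return 1e6, m / 1e6
    k = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        num = math.log(k) - special.digamma(k) - s
        den = 1.0 / k - special.polygamma(1, k)
        step = num / den
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-10 * k:
            k = k_new
            break
        k = k_new
    k = min(max(k, 1e-3), 1e6)
    return k, m / k


def fit_gamma_mixture(
    values: np.ndarray,
    seed: int | None = 0,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> GammaMixture:
    """Fit a 2-component gamma mixture (plus zero mass) by EM.

    ``zero_mass`` is the fraction of values ≤ 0; EM runs on the positive
    values with a quantile-split initialization and seeded jittered
    restarts, converging on mean log-likelihood change < ``tol``.  Raises
    :class:`FitError` (carrying the best parameters seen) when no restart
    converges, and ``ValueError`` on insufficient or degenerate data.

    The two-component family nests the single gamma, where the weight
    split is unidentifiable (EM then mimics one gamma with two arbitrary
    similar components).  As a safeguard, the single-gamma MLE is also
    computed and, when BIC prefers it, the fit is returned in degenerate
    form: all continuous weight on component one, component two a
    zero-weight copy.  The family stays capped at two components.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 50:
        raise ValueError(f"need >= 50 values to fit, got {len(values)}")
    pos = values[values > 0]
    if len(pos) < 20:
        raise ValueError(f"need >= 20 positive values, got {len(pos)}")
    if np.ptp(pos) == 0:
        raise ValueError("degenerate sample: all positive values identical")
    zero_mass = 1.0 - len(pos) / len(values)
    rng = np.random.default_rng(seed)

    best_ll = -np.inf
    best: GammaMixture | None = None
    converged = False
    for restart in range(n_restarts):
        # quantile-split init: low/high halves around a (jittered) split point
        q = 0.5 if restart == 0 else float(rng.uniform(0.25, 0.75))
        split = np.quantile(pos, q)
        lo, hi = pos[pos <= split], pos[pos > split]
        if len(lo) < 2 or len(hi) < 2:
            lo, hi = pos[: len(pos) // 2], pos[len(pos) // 2 :]
        params = []
        for part in (lo, hi):
            m, v = part.mean(), max(part.var(), 1e-12)
            k = min(max(m * m / v, 1e-2), 1e4)
            params.append((k, m / k))
        shapes = np.array([p[0] for p in params])
        scales = np.array([p[1] for p in params])
        w = np.array([len(lo), len(hi)], dtype=float)
        w /= w.sum()

        prev_ll = -np.inf
        ok = False
        for _ in range(max_iter):
            comp = np.stack(
                [
                    w[k] * stats.gamma.pdf(pos, a=shapes[k], scale=scales[k])
                    for k in (0, 1)
                ]
            )
            total = comp.sum(axis=0)
            total = np.maximum(total, 1e-300)
            ll = float(np.log(total).mean())
            resp = comp / total
            w = resp.mean(axis=1)
            w = np.maximum(w, 1e-8)
            w /= w.sum()
            for k in (0, 1):
                shapes[k], scales[k] = _gamma_mle(pos, resp[k])
            if abs(ll - prev_ll) < tol:
                ok = True
                break
            prev_ll = ll
        if ll > best_ll:
            best_ll = ll
            order = np.argsort(shapes * scales)  # low-mean component first
            best = GammaMixture(
                weights=w[order] * (1.0 - zero_mass),
                shapes=shapes[order],
                scales=scales[order],
                zero_mass=zero_mass,
            )
            converged = converged or ok
        elif ok:
            converged = True
    if best is None:
        raise FitError("EM produced no valid parameters")
    if not converged:
        raise FitError(
            f"EM did not converge in {n_restarts} restarts x {max_iter} iterations",
            best=best,
        )
    # parsimony: prefer the nested single gamma when BIC says the second
    # component only models sampling noise (5 vs 2 free parameters)
    k1, s1 = _gamma_mle(pos, np.ones_like(pos))
    ll1 = float(stats.gamma.logpdf(pos, a=k1, scale=s1).mean())
    n_pos = len(pos)
    if 2.0 * n_pos * (best_ll - ll1) < 3.0 * math.log(n_pos):
        return GammaMixture(
            weights=np.array([1.0 - zero_mass, 0.0]),
            shapes=np.array([k1, k1]),
            scales=np.array([s1, s1]),
            zero_mass=zero_mass,
        )
    return best


# ---------------------------------------------------------------------------
# structural information


@dataclass
class StructureModels:
    """Paired/unpaired reactivity likelihoods per nucleotide type.

    ``models[base] = (paired: GammaMixture, unpaired: GammaMixture)``.
    Bases may be absent (e.g. two-base A/C-only probing).
    """

    models: dict[str, tuple[GammaMixture, GammaMixture]] = field(default_factory=dict)

    def bases(self) -> set[str]:
        return set(self.models)

    def paired(self, base: str) -> GammaMixture:
        return self.models[base][0]

    def unpaired(self, base: str) -> GammaMixture:
        return self.models[base][1]

    def to_json(self) -> str:
        return json.dumps(
            {
                b: {"paired": p.to_dict(), "unpaired": u.to_dict()}
                for b, (p, u) in sorted(self.models.items())
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StructureModels":
        raw = json.loads(text)
        return cls(
            {
                b: (
                    GammaMixture.from_dict(d["paired"]),
                    GammaMixture.from_dict(d["unpaired"]),
                )
                for b, d in raw.items()
            }
        )


@dataclass
class ESIResult:
    """Per-position structural information and its molecule-wide mean."""

    si: np.ndarray  # bits; NaN at masked positions
    esi: float  # mean SI over unmasked positions, bits
    n_used: int


def posterior_paired(
    r: float, paired_model: GammaMixture, unpaired_model: GammaMixture
) -> float:
    """Posterior probability of being paired given reactivity r.

    Equal-prior form: p(b|r) = p̂(r|b) / (p̂(r|b) + p̂(r|u)); with equal
    class likelihoods this returns the 0.5 no-data prior.
    """
    lb = float(paired_model.likelihood(r))
    lu = float(unpaired_model.likelihood(r))
    if lb + lu < DENSITY_FLOOR:
        # 0/0 guard: treat vanishing evidence as the no-data prior
        if lb == lu:
            return 0.5
        lb, lu = max(lb, DENSITY_FLOOR**2), max(lu, DENSITY_FLOOR**2)
    return lb / (lb + lu)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(special.xlogy(p, p) + special.xlogy(1 - p, 1 - p)) / math.log(2)
    return h


def structural_information(
    r, paired_model: GammaMixture, unpaired_model: GammaMixture
) -> np.ndarray | float:
    """Structural information SI(r) = 1 − H(s|r), in bits, in [0, 1].

    SI is 0 where the two class likelihoods are equal (posterior 0.5) and
    1 where only one class has nonzero likelihood.  Where both likelihoods
    vanish (below the 1e-12 floor), SI is 0 with a warning — there is no
    basis for a posterior, so the no-data prior stands.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    lb = np.atleast_1d(paired_model.likelihood(r_arr))
    lu = np.atleast_1d(unpaired_model.likelihood(r_arr))
    both_zero = (lb + lu) < DENSITY_FLOOR
    if both_zero.any():
        warnings.warn(
            f"both class likelihoods vanish at {int(both_zero.sum())} "
            "reactivities; SI set to 0 there",
            stacklevel=2,
        )
    denom = np.where(both_zero, 1.0, lb + lu)
    pb = lb / denom
    si = 1.0 - _binary_entropy(pb)
    si = np.where(both_zero, 0.0, np.clip(si, 0.0, 1.0))
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(si[0])
    return si


def expected_structural_information(
    profile: ReactivityProfile,
    models: StructureModels,
    structure: ReferenceStructure | None = None,
    bases: set[str] | str = "ACGU",
) -> ESIResult:
    """Expected structural information: mean SI over unmasked positions.

    Positions whose base is outside ``bases`` (e.g. G and U in two-base
    A/C-only mode) contribute SI = 0 but stay in the denominator, so
    two-base ESI is directly comparable with four-base ESI.  ``structure``
    is accepted for length validation only — SI depends on the fitted
    likelihood models, not on the reference pairing at each position.
    """
    bases = set(bases)
    if structure is not None and len(structure) != len(profile):
        raise ValueError("structure length != profile length")
    if profile.reactivity is None:
        raise ValueError("profile has no reactivities")
    missing = {
        b for b in bases if b in set(profile.sequence) and b not in models.bases()
    }
    if missing:
        raise ValueError(f"no fitted models for requested bases: {sorted(missing)}")
    base_arr = profile.base_array()
    si = np.full(len(profile), np.nan)
    for base in "ACGU":
        sel = (base_arr == base) & profile.mask
        if not sel.any():
            continue
        if base in bases:
            si[sel] = structural_information(
                profile.reactivity[sel], models.paired(base), models.unpaired(base)
            )
        else:
            si[sel] = 0.0
    used = profile.mask & np.isfinite(si)
    n_used = int(used.sum())
    if n_used == 0:
        raise ValueError("no unmasked positions; ESI undefined")
    return ESIResult(si=si, esi=float(si[used].mean()), n_used=n_used)
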