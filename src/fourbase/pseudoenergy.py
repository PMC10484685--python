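"""Pseudo-energy potentials: nucleotide-specific paired/unpaired
reactivity likelihoods fitted from a normalized profile plus a known
structure, for use as folding restraints.

The log-likelihood ratio log(p̂(r|unpaired) / p̂(r|paired)) is the
pseudo-energy a thermodynamic folding engine adds per nucleotide; fitted
tables are written in a documented text dialect modeled on the
RNAstructure ``dists`` layout (byte-compatibility with RNAstructure's own
tables is out of scope here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .infometrics import FitError, GammaMixture, StructureModels, fit_gamma_mixture
from .reactivity import ReactivityProfile
from .structure_io import ReferenceStructure

__all__ = ["PotentialTable", "fit_potentials", "write_dists_file", "read_dists_file"]

MIN_CLASS_POSITIONS = 50


@dataclass
class PotentialTable:
    """Fitted paired/unpaired reactivity likelihoods per nucleotide type."""

    models: StructureModels
    provenance: str = ""

    def bases(self) -> set[str]:
        return self.models.bases()

    def log_likelihood_ratio(self, base: str, r) -> np.ndarray:
        """log(p̂(r|u) / p̂(r|b)), the per-nucleotide folding pseudo-energy."""
        lu = np.maximum(self.models.unpaired(base).likelihood(r), 1e-12)
        lb = np.maximum(self.models.paired(base).likelihood(r), 1e-12)
        return np.log(lu) - np.log(lb)


def fit_potentials(
    profile: ReactivityProfile,
    structure: ReferenceStructure,
    seed: int | None = 0,
) -> PotentialTable:
    """Fit double-gamma mixtures to each base's paired and unpaired
    normalized reactivities.

    A base needs at least 50 usable positions in *each* class; bases
    falling short are omitted with a warning.
    """
    if profile.reactivity is None:
        raise ValueError("profile must be normalized")
    if len(structure) != len(profile):
        raise ValueError("structure length != profile length")
    paired = structure.is_paired()
    bases = profile.base_array()
    models: dict[str, tuple[GammaMixture, GammaMixture]] = {}
    for base in "ACGU":
        fits = []
        for want_paired in (True, False):
            sel = (bases == base) & (paired == want_paired) & profile.mask
            vals = profile.reactivity[sel]
            cls = "paired" if want_paired else "unpaired"
            if len(vals) < MIN_CLASS_POSITIONS:
                warnings.warn(
                    f"{base}: only {len(vals)} {cls} positions "
                    f"(need {MIN_CLASS_POSITIONS}); base omitted",
                    stacklevel=2,
                )
                break
            try:
                fits.append(fit_gamma_mixture(vals, seed=seed))
            except (ValueError, FitError) as exc:
                warnings.warn(f"{base} {cls}: fit failed ({exc}); base omitted",
                              stacklevel=2)
                break
        else:
            models[base] = (fits[0], fits[1])
    return PotentialTable(StructureModels(models))


def write_dists_file(table: PotentialTable, path: str) -> None:
    """Write a potential table in the fourbase dists text dialect.

    Grammar: a version header, a provenance comment, then one block per
    base (A, C, G, U in order).  A fitted base block is seven lines: the
    ``base X`` line plus, for each class, three ``<class> <param> v1 v2``
    lines (weights, shapes, scales) and the class zero_mass folded into
    the weights line as a trailing value.  Unfitted bases get an explicit
    ``base X absent`` marker.
    """
    lines = ["# fourbase dists v1"]
    if table.provenance:
        lines.append(f"# provenance: {table.provenance}")
    for base in "ACGU":
        if base not in table.bases():
            lines.append(f"base {base} absent")
            continue
        lines.append(f"base {base}")
        for cls, model in (
            ("paired", table.models.paired(base)),
            ("unpaired", table.models.unpaired(base)),
        ):
            w = model.weights
            lines.append(
                f"{cls} weights {w[0]:.10g} {w[1]:.10g} {model.zero_mass:.10g}"
            )
            lines.append(
                f"{cls} shapes {model.shapes[0]:.10g} {model.shapes[1]:.10g}"
            )
            lines.append(
                f"{cls} scales {model.scales[0]:.10g} {model.scales[1]:.10g}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dists_file(path: str) -> PotentialTable:
    """Parse the dists dialect written by :func:`write_dists_file`."""
    provenance = ""
    models: dict[str, tuple[GammaMixture, GammaMixture]] = {}
    current: str | None = None
    buf: dict[str, dict[str, list[float]]] = {}

    def flush() -> None:
        if current is None:
            return
        parts = []
        for cls in ("paired", "unpaired"):
            p = buf[cls]
            parts.append(
                GammaMixture(
                    weights=np.array(p["weights"][:2]),
                    shapes=np.array(p["shapes"]),
                    scales=np.array(p["scales"]),
                    zero_mass=p["weights"][2],
                )
            )
        models[current] = (parts[0], parts[1])

    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("# fourbase dists"):
        raise ValueError(f"{path}: missing dists header")
    for ln in lines[1:]:
        if ln.startswith("# provenance:"):
            provenance = ln.split(":", 1)[1].strip()
        elif ln.startswith("#"):
            continue
        elif ln.startswith("base "):
            flush()
            toks = ln.split()
            if toks[-1] == "absent":
                current = None
            else:
                current = toks[1]
                buf = {"paired": {}, "unpaired": {}}
        else:
            toks = ln.split()
            cls, param, vals = toks[0], toks[1], [float(v) for v in toks[2:]]
            if current is None:
                raise ValueError(f"{path}: parameter line outside a base block: {ln!r}")
            buf[cls][param] = vals
    flush()
    return PotentialTable(StructureModels(models), provenance=provenance)
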