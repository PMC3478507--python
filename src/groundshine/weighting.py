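"""Effective dose from organ equivalent doses under ICRP tissue weighting.

Effective dose is the tissue-weighted, sex-averaged sum of organ equivalent
doses,

    E = sum_T w_T * (H_T^male + H_T^female) / 2,

with the remainder tissues aggregated (here: arithmetic mean of each sex's
designated remainder organs) before weighting.  Both the 2007 (ICRP 103) and
1990 (ICRP 60) weighting-factor sets are bundled, so coefficient sets can be
compared across the two definitions applied to the same organ doses.
Radiation weighting is trivial for photons (w_R = 1), so the inputs may be
absorbed organ doses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class TissueWeightScheme:
    """A named set of tissue weighting factors plus a remainder rule."""

    scheme_id: str
    weights: dict[str, float]
    remainder_members: dict[str, tuple[str, ...]]  # per sex
    remainder_rule: str = "unweighted arithmetic mean of remainder tissues"

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.scheme_id}: weights sum to {total}, not 1")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all tissue weights must be positive")

    def vocabulary(self, sex: str) -> set[str]:
        """Every tissue an OrganDoseSet must provide for this scheme and sex."""
        named = set(self.weights) - {"remainder"}
        return named | set(self.remainder_members.get(sex, ()))


@dataclass(frozen=True)
class OrganDoseSet:
    """Organ equivalent doses (Sv, or Sv/Gy when normalised) for one phantom sex."""

    sex: str
    doses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if any(d < 0 for d in self.doses.values()):
            raise ValueError("organ doses must be >= 0")

    @classmethod
    def from_csv(cls, path, sex: str) -> "OrganDoseSet":
        """Read one sex's doses from a CSV with columns tissue, sex, dose."""
        doses = {}
        with open(path) as fh:
            for row in csv.DictReader(
                    r for r in fh if not r.lstrip().startswith("#")):
                if row["sex"] == sex:
                    doses[row["tissue"]] = float(row["dose"])
        return cls(sex, doses)


def load_scheme(scheme_id: str) -> TissueWeightScheme:
    """Load a bundled weighting scheme ('icrp103' or 'icrp60')."""
    path = Path(resources.files("groundshine") / "data" / "tissue_weights"
                / f"{scheme_id}.csv")
    if not path.exists():
        raise ValueError(f"unknown weighting scheme {scheme_id!r}")
    weights: dict[str, float] = {}
    members: dict[str, list[str]] = {"male": [], "female": []}
    with open(path) as fh:
        for row in csv.DictReader(r for r in fh if not r.lstrip().startswith("#")):
            if row["kind"] == "weight":
                weights[row["tissue"]] = float(row["value"])
            elif row["kind"] == "member":
                sexes = ("male", "female") if row["sex"] == "both" else (row["sex"],)
                for s in sexes:
                    members[s].append(row["tissue"])
    return TissueWeightScheme(scheme_id, weights,
                              {s: tuple(m) for s, m in members.items()})


def _aggregated_doses(doses: OrganDoseSet, scheme: TissueWeightScheme) -> dict[str, float]:
    needed = scheme.vocabulary(doses.sex)
    missing = sorted(needed - set(doses.doses))
    if missing:
        raise ValueError(
            f"{doses.sex} dose set is missing tissues for {scheme.scheme_id}: "
            + ", ".join(missing))
    out = {t: doses.doses[t] for t in scheme.weights if t != "remainder"}
    if "remainder" in scheme.weights:
        members = scheme.remainder_members[doses.sex]
        out["remainder"] = sum(doses.doses[t] for t in members) / len(members)
    return out


def effective_dose(male: OrganDoseSet, female: OrganDoseSet,
                   scheme: TissueWeightScheme | str) -> float:
    """Sex-averaged tissue-weighted effective dose (same units as the inputs)."""
    if isinstance(scheme, str):
        scheme = load_scheme(scheme)
    hm = _aggregated_doses(male, scheme)
    hf = _aggregated_doses(female, scheme)
    return sum(w * 0.5 * (hm[t] + hf[t]) for t, w in scheme.weights.items())


def compare_schemes(male: OrganDoseSet, female: OrganDoseSet) -> float:
    """Ratio of effective doses, ICRP 103 definition over ICRP 60 definition."""
    e103 = effective_dose(male, female, load_scheme("icrp103"))
    e60 = effective_dose(male, female, load_scheme("icrp60"))
    return e103 / e60
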