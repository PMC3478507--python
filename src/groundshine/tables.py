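"""Analyses over the published coefficient tables for adults and the Baby.

The packaged fixtures transcribe the published effective-dose conversion
coefficients (Sv/h per Bq/m^2) for 72 radionuclides at 14 relaxation depths
(0-100 g/cm^2), for the reference adults and for an 8-week-old Baby phantom.
The functions here reproduce the body-size ratio statistics, depth
attenuation factors and ratio-distribution summaries reported for them.

The published study computed its distribution statistics over 185 nuclides;
only the printed 72-nuclide subset is available here, so all summary outputs
are labelled "subset".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .folding import CoefficientTable

#: the 14 printed relaxation depths, g/cm^2
PRINTED_ALPHAS = (0.0, 0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 3.0, 5.0,
                  10.0, 20.0, 30.0, 50.0, 100.0)


@dataclass
class RatioStats:
    """Summary of per-nuclide Baby/adult effective-dose ratios at one depth."""

    alpha: float
    ratios: pd.Series  # indexed by nuclide
    threshold: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    coverage: str = "subset"

    @property
    def max(self) -> float:
        return float(self.ratios.max())

    @property
    def mean(self) -> float:
        return float(self.ratios.mean())

    @property
    def fraction_below_threshold(self) -> float:
        return float((self.ratios < self.threshold).mean())

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "count": self.bin_counts,
        })


def _tables_dir() -> Path:
    return Path(resources.files("groundshine") / "data" / "tables")


def load_published_tables(verify_checksum: bool = True
                      ) -> tuple[CoefficientTable, CoefficientTable]:
    """Load the packaged printed coefficient tables (adult, baby).

    The fixture files are verified against recorded SHA-256 digests; a
    mismatch indicates a corrupted or edited transcription and is an error.
    Every nuclide row is checked to be non-increasing across the 14 printed
    depths (a violation would indicate a transcription error).
    """
    d = _tables_dir()
    sums = json.loads((d / "checksums.json").read_text())
    out = []
    for phantom, fname in (("adult", "adult.csv"), ("baby", "baby.csv")):
        path = d / fname
        if verify_checksum:
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            if digest != sums[fname]:
                raise ValueError(f"checksum mismatch for {fname}: {digest}")
        df = pd.read_csv(path, comment="#", dtype={"coefficient": str})
        entries = pd.DataFrame({
            "nuclide": df["nuclide"],
            "alpha_gcm2": df["alpha_gcm2"].astype(float),
            "coefficient": df["coefficient"].astype(float),
            "printed": df["coefficient"],  # verbatim provenance strings
        })
        wide = entries.pivot(index="nuclide", columns="alpha_gcm2",
                             values="coefficient")[list(PRINTED_ALPHAS)]
        bad = wide.index[(wide.diff(axis=1).iloc[:, 1:] > 0).any(axis=1)]
        if len(bad):
            raise ValueError(
                "printed rows increase with depth (transcription error?): "
                + ", ".join(bad))
        out.append(CoefficientTable(
            phantom=phantom, scheme="icrp103", entries=entries,
            provenance=f"published printed table, {wide.shape[0]} nuclides"))
    return out[0], out[1]


def body_size_ratio(adult: CoefficientTable, baby: CoefficientTable,
                    nuclide: str, alpha: float) -> float:
    """Baby/adult effective-dose ratio for one nuclide and relaxation depth."""
    return baby.value(nuclide, alpha) / adult.value(nuclide, alpha)


def depth_attenuation_factor(table: CoefficientTable, nuclide: str,
                             alpha_from: float = 0.0,
                             alpha_to: float = 5.0) -> float:
    """Coefficient at ``alpha_from`` divided by that at ``alpha_to``.

    With the defaults this is the factor by which increasing the relaxation
    depth from 0 to 5 g/cm^2 reduces the dose rate per unit deposit.
    """
    return table.value(nuclide, alpha_from) / table.value(nuclide, alpha_to)


def ratio_distribution(adult: CoefficientTable, baby: CoefficientTable,
                       alpha: float = 0.0, threshold: float = 1.5,
                       n_bins: int = 12) -> RatioStats:
    """Distribution of Baby/adult ratios over the shared nuclide set.

    ``threshold`` expresses "within X-fold body-size difference" as
    ratio < threshold (the Baby coefficients exceed the adult ones
    throughout the printed tables).
    """
    shared = sorted(set(adult.nuclides) & set(baby.nuclides))
    if not shared:
        raise ValueError("tables share no nuclides")
    ratios = pd.Series(
        {n: body_size_ratio(adult, baby, n, alpha) for n in shared})
    if np.any(ratios <= 0):
        raise ValueError("non-positive ratio encountered")
    counts, edges = np.histogram(ratios.to_numpy(), bins=n_bins)
    return RatioStats(alpha=alpha, ratios=ratios, threshold=threshold,
                      bin_edges=edges, bin_counts=counts)
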