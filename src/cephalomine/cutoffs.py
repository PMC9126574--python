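"""Stratified head-circumference cutoffs and microcephaly classification.

Step two of the cutoff definition: within each sex × height stratum,
microcephaly is an HC strictly below mean − 2·SD of that stratum.
Height strata are half-open 10 cm bins (lower edge inclusive):
[-inf, 1.60), [1.60, 1.70), [1.70, 1.80), [1.80, inf) metres.

Cutoffs are kept at full precision; one-decimal rounding belongs to the
reporting layer only. The SD uses the n − 1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, StratumError

__all__ = [
    "DEFAULT_BIN_EDGES",
    "StratumStats",
    "CutoffTable",
    "compute_cutoff",
    "build_cutoff_table",
    "classify_microcephaly",
    "classify_cohort",
    "prevalence",
    "PrevalenceResult",
]

#: Interior height bin edges (metres); the outer edges are -inf / +inf.
DEFAULT_BIN_EDGES: tuple[float, ...] = (1.60, 1.70, 1.80)

_SEXES = ("female", "male")

_TABLE_COLUMNS = ("sex", "bin_low_m", "bin_high_m", "n", "mean_hc_cm", "sd_hc_cm", "cutoff_cm")


def compute_cutoff(mean_hc: float, sd_hc: float) -> float:
    """Microcephaly cutoff: mean − 2·SD, unrounded."""
    if sd_hc < 0:
        raise ConfigError(f"sd_hc must be >= 0, got {sd_hc}")
    return mean_hc - 2.0 * sd_hc


@dataclass(frozen=True)
class StratumStats:
    """Per-stratum HC statistics and the derived cutoff."""

    sex: str
    bin_low: float  # metres, inclusive (-inf for the lowest bin)
    bin_high: float  # metres, exclusive (inf for the highest bin)
    n: int
    mean_hc: float  # cm
    sd_hc: float  # cm
    cutoff: float  # cm, mean_hc - 2 * sd_hc at full precision

    @property
    def label(self) -> str:
        lo = "-inf" if math.isinf(self.bin_low) else f"{self.bin_low:.2f}"
        hi = "inf" if math.isinf(self.bin_high) else f"{self.bin_high:.2f}"
        return f"{self.sex} [{lo}, {hi})"


class CutoffTable:
    """All strata of one cohort plus lookup by (sex, height)."""

    def __init__(self, strata: list[StratumStats], bin_edges: tuple[float, ...]):
        self.strata = list(strata)
        self.bin_edges = tuple(bin_edges)
        self._by_key = {(s.sex, s.bin_low, s.bin_high): s for s in self.strata}

    @property
    def missing_strata(self) -> list[tuple[str, float, float]]:
        """Sex × bin cells with no subjects (absent from the table)."""
        missing = []
        for sex in _SEXES:
            for lo, hi in _iter_bins(self.bin_edges):
                if (sex, lo, hi) not in self._by_key:
                    missing.append((sex, lo, hi))
        return missing

    def lookup(self, sex: str, height_m: float) -> StratumStats:
        if sex not in _SEXES:
            raise StratumError(f"unknown sex code {sex!r}")
        lo, hi = _find_bin(self.bin_edges, height_m)
        stratum = self._by_key.get((sex, lo, hi))
        if stratum is None:
            raise StratumError(
                f"no stratum for sex={sex!r}, height {height_m} m "
                f"(bin [{lo}, {hi}) absent from table)"
            )
        return stratum

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sex": s.sex,
                    "bin_low_m": s.bin_low,
                    "bin_high_m": s.bin_high,
                    "n": s.n,
                    "mean_hc_cm": s.mean_hc,
                    "sd_hc_cm": s.sd_hc,
                    "cutoff_cm": s.cutoff,
                }
                for s in self.strata
            ],
            columns=list(_TABLE_COLUMNS),
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, bin_edges=DEFAULT_BIN_EDGES) -> "CutoffTable":
        missing = sorted(set(_TABLE_COLUMNS) - set(frame.columns))
        if missing:
            raise SchemaError("cutoff table missing column(s): " + ", ".join(missing))
        strata = [
            StratumStats(
                sex=str(row.sex),
                bin_low=float(row.bin_low_m),
                bin_high=float(row.bin_high_m),
                n=int(row.n),
                mean_hc=float(row.mean_hc_cm),
                sd_hc=float(row.sd_hc_cm),
                cutoff=float(row.cutoff_cm),
            )
            for row in frame.itertuples()
        ]
        return cls(strata, bin_edges)

    @classmethod
    def read_csv(cls, path, bin_edges=DEFAULT_BIN_EDGES) -> "CutoffTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(frame, bin_edges)


def _iter_bins(edges: tuple[float, ...]):
    bounds = (-math.inf, *edges, math.inf)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        yield lo, hi


def _find_bin(edges: tuple[float, ...], height_m: float) -> tuple[float, float]:
    for lo, hi in _iter_bins(edges):
        if lo <= height_m < hi:
            return lo, hi
    raise StratumError(f"height {height_m} m falls in no bin")


def build_cutoff_table(
    cohort: pd.DataFrame, bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
) -> CutoffTable:
    """Compute per-stratum HC mean, SD (n − 1) and mean − 2SD cutoff.

    Empty strata are omitted (and listed by ``missing_strata``); a
    stratum with a single subject raises :class:`StratumError`, since
    its SD is undefined.
    """
    edges = tuple(sorted(bin_edges))
    strata: list[StratumStats] = []
    for sex in _SEXES:
        sub = cohort[cohort["sex"] == sex]
        heights = sub["height_m"].to_numpy(dtype=float)
        hcs = sub["hc_cm"].to_numpy(dtype=float)
        for lo, hi in _iter_bins(edges):
            mask = (heights >= lo) & (heights < hi)
            n = int(mask.sum())
            if n == 0:
                continue
            if n < 2:
                raise StratumError(
                    f"stratum {sex} [{lo}, {hi}) has n = 1; SD undefined"
                )
            values = hcs[mask]
            mean = float(values.mean())
            sd = float(values.std(ddof=1))
            strata.append(
                StratumStats(
                    sex=sex,
                    bin_low=lo,
                    bin_high=hi,
                    n=n,
                    mean_hc=mean,
                    sd_hc=sd,
                    cutoff=compute_cutoff(mean, sd),
                )
            )
    return CutoffTable(strata, edges)


def classify_microcephaly(subject, table: CutoffTable) -> bool:
    """True iff the subject's HC is strictly below its stratum cutoff.

    ``subject`` is any mapping (or DataFrame row) with ``sex``,
    ``height_m`` and ``hc_cm``.
    """
    stratum = table.lookup(str(subject["sex"]), float(subject["height_m"]))
    return float(subject["hc_cm"]) < stratum.cutoff


def classify_cohort(cohort: pd.DataFrame, table: CutoffTable) -> np.ndarray:
    """Vectorised :func:`classify_microcephaly` over a cohort; 0/1 array."""
    flags = np.empty(len(cohort), dtype=np.int64)
    sexes = cohort["sex"].to_numpy()
    heights = cohort["height_m"].to_numpy(dtype=float)
    hcs = cohort["hc_cm"].to_numpy(dtype=float)
    cache: dict[tuple[str, tuple[float, float]], float] = {}
    for i in range(len(cohort)):
        key = (sexes[i], _find_bin(table.bin_edges, heights[i]))
        if key not in cache:
            cache[key] = table.lookup(sexes[i], heights[i]).cutoff
        flags[i] = int(hcs[i] < cache[key])
    return flags


@dataclass(frozen=True)
class PrevalenceResult:
    count: int
    total: int

    @property
    def proportion(self) -> float:
        return self.count / self.total if self.total else 0.0


def prevalence(cohort: pd.DataFrame, table: CutoffTable) -> PrevalenceResult:
    """Microcephaly count and proportion in a cohort."""
    flags = classify_cohort(cohort, table)
    return PrevalenceResult(count=int(flags.sum()), total=len(cohort))
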