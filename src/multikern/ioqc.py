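"""I/O and quality control for genotypes, phenotype tables, and weather.

Marker QC mirrors the standard GBS cleaning rules for this kind of panel:
markers with more than 80% missing calls, minor allele frequency below 0.05,
or heterozygosity above 10% are discarded. Missing dosages are then filled
with the per-marker mean of the observed calls (which preserves allele
frequency, the only property the cross-product kernel needs).

Daily weather is summarized to environmental covariates (ECs) as 10-day
interval means over the November 11 - May 11 growing window, six variables
per interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "QCReport",
    "read_genotypes",
    "write_genotypes_tsv",
    "marker_qc",
    "impute_missing",
    "aggregate_ecs",
    "EC_VARIABLES",
]

EC_VARIABLES = ("t_avg_C", "t_min_C", "t_max_C", "rel_hum", "rain_cm", "solrad")


@dataclass
class MarkerMatrix:
    """Lines x markers dosage table (0/1/2 of the alternate allele).

    Missing calls are NaN. Per-marker minor-allele frequency, missing rate
    and heterozygosity rate are recomputed from the dosages on demand.
    """

    line_ids: list
    marker_ids: list
    dosages: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line IDs")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker IDs")
        if self.dosages.size == 0:
            raise ValueError("empty marker matrix")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.dosages) & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
        # imputed matrices carry fractional dosages; only raw input is checked
        self._raw_calls = not bad.any()

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def alt_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency among observed calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency: alternate frequency folded at 0.5."""
        p = self.alt_freq
        return np.minimum(p, 1.0 - p)

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    @property
    def het_rate(self) -> np.ndarray:
        """Fraction of heterozygous (dosage 1) calls among observed calls."""
        obs = ~np.isnan(self.dosages)
        het = (self.dosages == 1.0) & obs
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, het.sum(axis=0) / n_obs, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids,
                            columns=self.marker_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MarkerMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(float))

    def subset_markers(self, keep: np.ndarray) -> "MarkerMatrix":
        ids = [m for m, k in zip(self.marker_ids, keep) if k]
        return MarkerMatrix(self.line_ids, ids, self.dosages[:, np.asarray(keep, bool)])

    def subset_lines(self, lines) -> "MarkerMatrix":
        idx = {l: i for i, l in enumerate(self.line_ids)}
        rows = [idx[l] for l in lines]
        return MarkerMatrix(list(lines), self.marker_ids, self.dosages[rows])


@dataclass
class QCReport:
    """Per-criterion removal counts from marker QC."""

    n_input: int
    n_retained: int
    removed_missing: int
    removed_maf: int
    removed_het: int
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def read_genotypes(path, format: str = "tsv") -> MarkerMatrix:
    """Read a genotype matrix from VCF or a lines x markers dosage TSV.

    VCF: biallelic SNP records only (multiallelic records are skipped with a
    logged count); GT is converted to the alternate-allele dosage, missing
    GT to NaN; marker order follows file order.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return MarkerMatrix.from_dataframe(df)
    if format != "vcf":
        raise ValueError(f"unknown format {format!r}")

    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    lines = list(vcf.samples)
    marker_ids, cols = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        marker_ids.append(mid)
        gt = var.gt_types.astype(float)  # 0,1,2, 3=missing under gts012
        gt[gt == 3] = np.nan
        cols.append(gt)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic record(s)")
    if not cols:
        raise ValueError("no biallelic records in VCF")
    return MarkerMatrix(lines, marker_ids, np.column_stack(cols))


def write_genotypes_tsv(m: MarkerMatrix, path) -> None:
    m.to_dataframe().to_csv(path, sep="\t")


def marker_qc(m: MarkerMatrix, max_missing: float = 0.80, min_maf: float = 0.05,
              max_het: float = 0.10) -> tuple[MarkerMatrix, QCReport]:
    """Filter markers by missingness, minor allele frequency and heterozygosity.

    A marker is retained iff missing_rate <= max_missing AND maf >= min_maf
    AND het_rate <= max_het (boundaries survive: the removal rules are the
    strict inequalities "more than", "below", "larger than"). The criteria
    are applied jointly, so the result is order-independent.
    """
    for name, t in (("max_missing", max_missing), ("min_maf", min_maf),
                    ("max_het", max_het)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    miss, maf, het = m.missing_rate, m.maf, m.het_rate
    fail_miss = miss > max_missing
    # markers with zero observed calls have undefined maf/het: drop via missing
    fail_maf = np.where(np.isnan(maf), False, maf < min_maf)
    fail_het = np.where(np.isnan(het), False, het > max_het)
    keep = ~(fail_miss | fail_maf | fail_het)
    report = QCReport(
        n_input=m.n_markers,
        n_retained=int(keep.sum()),
        removed_missing=int(fail_miss.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_het=int(fail_het.sum()),
        thresholds={"max_missing": max_missing, "min_maf": min_maf,
                    "max_het": max_het},
    )
    if report.n_retained == 0:
        counts = {"missing": report.removed_missing, "maf": report.removed_maf,
                  "het": report.removed_het}
        worst = max(counts, key=counts.get)
        raise ValueError(
            f"marker QC removed all {m.n_markers} markers "
            f"(dominant criterion: {worst})")
    return m.subset_markers(keep), report


def impute_missing(m: MarkerMatrix, method: str = "column_mean") -> MarkerMatrix:
    """Fill missing dosages with the per-marker mean of observed calls.

    The imputed values are continuous (not rounded back to 0/1/2); a matrix
    with no missing cells is returned unchanged.
    """
    if method != "column_mean":
        raise ValueError(f"unknown imputation method {method!r}")
    miss = np.isnan(m.dosages)
    if not miss.any():
        return m
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = [mid for mid, n in zip(m.marker_ids, n_obs) if n == 0]
        raise ValueError(f"marker(s) with zero observed calls: {bad[:5]}")
    means = np.nanmean(m.dosages, axis=0)
    filled = np.where(miss, means[None, :], m.dosages)
    return MarkerMatrix(m.line_ids, m.marker_ids, filled)


def _season_window(dates: pd.Series, window: tuple[str, str]):
    """Return the start date implied by the window for a block of daily rows."""
    start_md = pd.to_datetime(window[0], format="%m-%d")
    return start_md.month, start_md.day


def aggregate_ecs(weather: pd.DataFrame, window: tuple[str, str] = ("11-11", "05-11"),
                  interval_days: int = 10, partial: str = "keep",
                  rainfall: str = "mean") -> pd.DataFrame:
    """Aggregate daily weather to 10-day-interval EC means per environment.

    Parameters
    ----------
    weather
        Daily table with columns ``env``, ``date`` and the six EC variables.
    window
        (start, end) as "MM-DD"; the growing window runs from the start
        month-day (in the calendar year before harvest when the start month
        is after the end month) through the end month-day.
    partial
        ``"keep"`` retains the trailing short interval as its own feature
        (default); ``"drop"`` discards days beyond the last complete interval.
    rainfall
        ``"mean"`` averages daily rainfall like every other variable;
        ``"sum"`` totals it per interval instead.

    Returns
    -------
    DataFrame env x feature, features named ``<variable>_<interval>`` in
    variable-major order.
    """
    if partial not in ("keep", "drop"):
        raise ValueError("partial must be 'keep' or 'drop'")
    if rainfall not in ("mean", "sum"):
        raise ValueError("rainfall must be 'mean' or 'sum'")
    missing_cols = [v for v in EC_VARIABLES if v not in weather.columns]
    if missing_cols:
        raise ValueError(f"weather table lacks variables: {missing_cols}")

    sm, sd_ = (int(x) for x in window[0].split("-"))
    em, ed = (int(x) for x in window[1].split("-"))

    rows = {}
    n_intervals_ref = None
    for env, block in weather.groupby("env", sort=True):
        block = block.sort_values("date")
        dates = pd.to_datetime(block["date"])
        # harvest year = max year present; season start may be the prior year
        end_year = int(dates.dt.year.max())
        end = pd.Timestamp(end_year, em, ed)
        start_year = end_year if (sm, sd_) <= (em, ed) else end_year - 1
        start = pd.Timestamp(start_year, sm, sd_)
        in_win = (dates >= start) & (dates <= end)
        if not in_win.any():
            raise ValueError(f"no rows inside the window for env {env!r}")
        sub = block.loc[in_win.values].copy()
        offsets = (pd.to_datetime(sub["date"]) - start).dt.days.to_numpy()
        interval = offsets // interval_days
        n_days = (end - start).days + 1
        n_complete = n_days // interval_days
        n_int = n_complete + (1 if (partial == "keep" and n_days % interval_days)
                              else 0)
        feats = {}
        for var in EC_VARIABLES:
            vals = sub[var].to_numpy(float)
            for i in range(n_int):
                sel = interval == i
                expected = (interval_days if i < n_complete
                            else n_days - n_complete * interval_days)
                got = int(sel.sum() - np.isnan(vals[sel]).sum())
                if got == 0:
                    raise ValueError(
                        f"env {env!r}: interval {i + 1} of {var} has no data")
                if got < expected:
                    warnings.warn(
                        f"env {env!r}: interval {i + 1} of {var} has "
                        f"{got}/{expected} days; averaging available days")
                if var == "rain_cm" and rainfall == "sum":
                    feats[f"{var}_{i + 1}"] = float(np.nansum(vals[sel]))
                else:
                    feats[f"{var}_{i + 1}"] = float(np.nanmean(vals[sel]))
        rows[env] = feats
        n_intervals_ref = n_int

    out = pd.DataFrame.from_dict(rows, orient="index")
    order = [f"{v}_{i + 1}" for v in EC_VARIABLES for i in range(n_intervals_ref)]
    out = out.loc[sorted(rows), order]
    out.index.name = "env"
    return out
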