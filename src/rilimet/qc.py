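"""Feature filtering, internal-standard normalization and QC reporting.

The preprocessing contract mirrors routine pseudotargeted LC-MS practice:
metabolites are retained when they have less than 20% missing values
across study samples and a relative standard deviation (RSD = SD/mean,
sample SD with n-1 denominator) below 30% in the pooled QC injections;
peak areas are then normalized to each metabolite's assigned internal
standard (plasma) or to the internal standard and tissue weight (lung).
Both thresholds are strict "<" rules. Missing values are excluded from
every statistic and never imputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import SampleTable

RSD_THRESHOLDS = (0.10, 0.20, 0.30)


@dataclass
class QCReport:
    n_metabolites_in: int = 0
    n_removed_missing: int = 0
    n_removed_rsd: int = 0
    rsd_per_metabolite: dict = field(default_factory=dict)
    frac_rsd_lt: dict = field(default_factory=dict)
    qc_within_2sd: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_metabolites_in": self.n_metabolites_in,
                "n_removed_missing": self.n_removed_missing,
                "n_removed_rsd": self.n_removed_rsd,
                "rsd_per_metabolite": self.rsd_per_metabolite,
                "frac_rsd_lt": {str(k): v for k, v in self.frac_rsd_lt.items()},
                "qc_within_2sd": self.qc_within_2sd,
                "notes": self.notes}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rsd": pd.Series(self.rsd_per_metabolite)}) \
            .rename_axis("metabolite_id")


class NormalizationError(ValueError):
    pass


def normalize(table: SampleTable, mode: str) -> SampleTable:
    """Divide each measured channel by its sample's internal-standard
    value (``mode="is"``, plasma) and additionally by tissue weight in mg
    (``mode="is_weight"``, lung). IS columns are dropped from the output;
    missing stays missing.
    """
    if table.normalized != "raw":
        raise NormalizationError("table is already normalized "
                                 f"({table.normalized})")
    tissues = set(table.samples["tissue"].dropna().unique())
    if mode == "is" and tissues == {"lung"}:
        raise NormalizationError("lung tables require mode='is_weight'")
    if mode == "is_weight" and tissues == {"plasma"}:
        raise NormalizationError("mode='is_weight' applies to lung tissue, "
                                 "not plasma")
    if mode not in ("is", "is_weight"):
        raise NormalizationError(f"unknown normalization mode {mode!r}")

    is_ids = table.is_channel_ids
    measured = table.measured_ids
    ab = table.abundance
    chan_of = table.metabolites.loc[measured, "is_channel"]
    missing_chan = chan_of[chan_of.isna() | ~chan_of.isin(ab.columns)]
    if len(missing_chan):
        raise NormalizationError("metabolites without a usable is_channel: "
                                 f"{list(missing_chan.index)[:5]}")
    for c in is_ids:
        col = ab[c]
        bad = col.index[col.isna() | (col == 0)].tolist()
        if bad:
            raise NormalizationError(f"internal standard {c} is zero or "
                                     f"missing for samples {bad[:5]}")
    out = ab[measured].copy()
    for c in is_ids:
        cols = chan_of.index[chan_of == c]
        out[cols] = out[cols].div(ab[c], axis=0)
    state = "is_normalized"
    if mode == "is_weight":
        w = table.samples["tissue_weight_mg"]
        bad = w.index[w.isna() | (w <= 0)].tolist()
        if bad:
            raise NormalizationError("tissue_weight_mg missing or "
                                     f"nonpositive for samples {bad[:5]}")
        out = out.div(w, axis=0)
        state = "is_weight_normalized"
    meta_out = table.metabolites.loc[measured].copy()
    meta_out["is_channel"] = np.nan  # consumed by normalization
    return SampleTable(out, table.samples.copy(), meta_out, state)


def _qc_rsd(table: SampleTable, ids) -> pd.Series:
    """RSD = sample SD / mean over QC injections, missing excluded."""
    qc = table.abundance.loc[table.qc_mask(), ids]
    if qc.shape[0] < 2:
        raise ValueError("at least 2 QC samples are required")
    mean = qc.mean(axis=0, skipna=True)
    sd = qc.std(axis=0, ddof=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    return rsd


def qc_filter(table: SampleTable, max_missing: float = 0.20,
              max_rsd: float = 0.30) -> tuple:
    """Apply the missingness and QC-RSD retention rules.

    A metabolite is retained iff its missing fraction over study samples
    is < ``max_missing`` AND its QC RSD is < ``max_rsd``. A metabolite
    failing both rules is counted once, under missingness. Metabolites
    whose QC mean is zero or undefined are removed with a note.
    Idempotent: filtering a filtered table removes nothing.
    """
    for thr in (max_missing, max_rsd):
        if not (0 < thr <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
    ids = table.measured_ids
    study = table.abundance.loc[table.study_mask(), ids]
    miss_frac = study.isna().mean(axis=0)
    rsd = _qc_rsd(table, ids)
    report = QCReport(n_metabolites_in=len(ids))
    keep = []
    for m in ids:
        if miss_frac[m] >= max_missing:
            report.n_removed_missing += 1
            continue
        if not np.isfinite(rsd[m]):
            report.n_removed_rsd += 1
            report.notes.append(f"{m}: undefined QC RSD (zero or missing "
                                "QC mean)")
            continue
        if rsd[m] >= max_rsd:
            report.n_removed_rsd += 1
            continue
        keep.append(m)
    finite = rsd[np.isfinite(rsd)]
    report.rsd_per_metabolite = {m: float(v) for m, v in rsd.items()
                                 if np.isfinite(v)}
    report.frac_rsd_lt = {t: float((finite < t).mean()) if len(finite) else 0.0
                          for t in RSD_THRESHOLDS}
    kept = table.subset(metabolite_ids=keep + table.is_channel_ids)
    return kept, report


def qc_summary(table: SampleTable) -> QCReport:
    """QC stability report: fraction of metabolites with QC RSD below
    10/20/30%, and a first-principal-component band check flagging each
    QC injection whose PC1 score lies within mean(QC scores) +/- 2 * SD
    of all samples' PC1 scores (unit-variance scaling, model fit on
    study + QC together)."""
    ids = table.measured_ids
    rsd = _qc_rsd(table, ids)
    finite = rsd[np.isfinite(rsd)]
    report = QCReport(n_metabolites_in=len(ids))
    report.rsd_per_metabolite = {m: float(v) for m, v in rsd.items()
                                 if np.isfinite(v)}
    report.frac_rsd_lt = {t: float((finite < t).mean()) if len(finite) else 0.0
                          for t in RSD_THRESHOLDS}

    X = table.abundance[ids].to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    Xs = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    scores = PCA(n_components=1, svd_solver="full").fit_transform(Xs)[:, 0]
    qc_idx = np.flatnonzero(table.qc_mask().to_numpy())
    qc_scores = scores[qc_idx]
    center = qc_scores.mean()
    band = 2.0 * scores.std(ddof=1)
    report.qc_within_2sd = {
        table.abundance.index[i]: bool(abs(scores[i] - center) <= band)
        for i in qc_idx}
    return report
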