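"""Cross-tissue marker-panel selection, OSC-KPLS injury triage and
trajectory analysis.

The selection cascade is a filtration: metabolites differential in both
lung (terminal day) and plasma (union over sampling days) form the
intersection stage; a 2-component PLS-DA per tissue keeps those with
VIP > 1 (in either tissue by default); a lung-vs-plasma Pearson
correlation stage annotates (and can filter on) cross-tissue agreement;
a final PLS-DA re-fit ranks survivors by VIP and keeps the top k
(default 7).

Triage maps the dose groups to ordinal injury classes
(0 Gy -> Control, 10 -> Mild, 20 -> Moderate, 35 -> Severe) and
evaluates the panel with an OSC-filtered Gaussian kernel PLS classifier
under leave-one-out (default) or k-fold cross-validation, together with
a parallel continuous-dose KPLS regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chemometrics import KPLSModel, PLSModel, impute_mean, osc_filter, \
    scale_matrix
from .datamodel import SampleTable

DEFAULT_TRIAGE_MAP = {0.0: "Control", 10.0: "Mild", 20.0: "Moderate",
                      35.0: "Severe"}
TRIAGE_CLASSES = ("Control", "Mild", "Moderate", "Severe")


# ---------------------------------------------------------------------------
# set stages


def union_differential(results) -> set:
    """Union of significant metabolites over a list of DiffResults
    (e.g. the per-day plasma screens)."""
    results = list(results)
    if not results:
        raise ValueError("need at least one DiffResult")
    out = set()
    for r in results:
        out |= set(r.significant_ids)
    return out


def intersect_tissues(lung_set, plasma_set) -> set:
    """Metabolites significant in both tissues."""
    inter = set(lung_set) & set(plasma_set)
    if not inter:
        warnings.warn("empty lung/plasma intersection", stacklevel=2)
    return inter


# ---------------------------------------------------------------------------
# panel object


@dataclass
class MarkerPanel:
    """Ordered marker selection with per-stage provenance."""

    stage: str                      # intersection | vip | correlation | final
    frame: pd.DataFrame             # index metabolite_id
    k: int = None

    @property
    def members(self) -> list:
        return self.frame.index.tolist()

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def to_dict(self) -> dict:
        return {"stage": self.stage, "k": self.k,
                "metabolites": self.frame.to_dict(orient="index")}


def _dose_class_labels(table: SampleTable, mapping=None):
    mapping = DEFAULT_TRIAGE_MAP if mapping is None else mapping
    doses = table.samples.loc[table.study_mask(), "dose_gy"]
    return [triage_map(d, mapping) for d in doses]


def _study_matrix(table: SampleTable, metabolites):
    sel = table.study_mask()
    X = table.abundance.loc[sel, list(metabolites)].to_numpy(dtype=float)
    return X


def _fit_plsda_vip(table: SampleTable, metabolites, n_components: int):
    X = _study_matrix(table, metabolites)
    labels = _dose_class_labels(table)
    ncomp = min(n_components, X.shape[1], X.shape[0] - 1)
    res = PLSModel(X, labels, classes=True).fit(ncomp)
    return pd.Series(res.vip(), index=list(metabolites))


def vip_screen(candidates, lung: SampleTable, plasma: SampleTable,
               n_components: int = 2, threshold: float = 1.0,
               rule: str = "either", min_keep: int = None) -> MarkerPanel:
    """Keep candidates with PLS-DA VIP > threshold, fitting a
    2-component dose-class model per tissue on the candidate columns.
    ``rule`` decides whether a candidate must exceed the threshold in
    ``either`` (default) or ``both`` tissues.

    Because mean(VIP^2) = 1 by construction, the VIP > 1 rule always
    removes roughly half of an equally-informative candidate set; when
    ``min_keep`` is given, the stage therefore keeps at least that many
    candidates, filling by descending max(vip_lung, vip_plasma), so the
    downstream top-k selection stays feasible (the stage is a
    pre-thinning, not the final selector).
    """
    candidates = sorted(candidates)
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate metabolites for a PLS-DA")
    vip_lung = _fit_plsda_vip(lung, candidates, n_components)
    vip_plasma = _fit_plsda_vip(plasma, candidates, n_components)
    if rule == "either":
        keep = (vip_lung > threshold) | (vip_plasma > threshold)
    elif rule == "both":
        keep = (vip_lung > threshold) & (vip_plasma > threshold)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if min_keep is not None and keep.sum() < min_keep:
        best = pd.concat([vip_lung, vip_plasma], axis=1).max(axis=1)
        top = best.sort_index().sort_values(ascending=False,
                                            kind="stable")
        keep.loc[top.index[:min(min_keep, len(top))]] = True
    frame = pd.DataFrame({"vip_lung": vip_lung, "vip_plasma": vip_plasma})
    frame.index.name = "metabolite_id"
    frame = frame.loc[keep[keep].index]
    return MarkerPanel(stage="vip", frame=frame)


def cross_tissue_corr(lung: SampleTable, plasma: SampleTable,
                      candidates) -> dict:
    """Pearson r (and two-sided p) between lung and plasma levels of
    each candidate across animals present in both tables."""
    sl = lung.samples.loc[lung.study_mask()]
    sp = plasma.samples.loc[plasma.study_mask()]
    common = sorted(set(sl["animal_id"]) & set(sp["animal_id"]))
    if len(common) < 3:
        raise ValueError("fewer than 3 animals matched across tissues")
    il = sl.index[sl["animal_id"].isin(common)]
    ip = sp.index[sp["animal_id"].isin(common)]
    lv = lung.abundance.loc[il].set_axis(sl.loc[il, "animal_id"], axis=0) \
        .sort_index()
    pv = plasma.abundance.loc[ip].set_axis(sp.loc[ip, "animal_id"], axis=0) \
        .sort_index()
    out = {}
    for m in candidates:
        pair = pd.concat([lv[m], pv[m]], axis=1, keys=["lung", "plasma"]) \
            .dropna()
        if len(pair) < 3:
            out[m] = (np.nan, np.nan)
            continue
        r, p = sps.pearsonr(pair["lung"], pair["plasma"])
        out[m] = (float(r), float(p))
    return out


def select_panel(screened: MarkerPanel, corr: dict, plasma: SampleTable,
                 k: int = 7, r_min: float = 0.0,
                 n_components: int = 2) -> MarkerPanel:
    """Final stage: filter on |cross-tissue r| >= r_min (default 0:
    annotate only), re-fit a PLS-DA on the survivors in plasma, rank by
    VIP (ties broken lexically) and keep the top k."""
    if screened.stage not in ("vip", "correlation"):
        raise ValueError("select_panel expects a vip/correlation-stage panel")
    frame = screened.frame.copy()
    frame["cross_tissue_r"] = [corr.get(m, (np.nan, np.nan))[0]
                               for m in frame.index]
    frame["cross_tissue_p"] = [corr.get(m, (np.nan, np.nan))[1]
                               for m in frame.index]
    survivors = frame.index[frame["cross_tissue_r"].abs() >= r_min].tolist()
    if k > len(survivors):
        raise ValueError(f"k={k} exceeds the {len(survivors)} surviving "
                         "candidates")
    vip_final = _fit_plsda_vip(plasma, survivors, n_components)
    frame = frame.loc[survivors]
    frame["vip_final"] = vip_final
    # descending VIP; stable sort on a lexically pre-sorted index breaks
    # ties alphabetically
    frame = frame.sort_index().sort_values("vip_final", ascending=False,
                                           kind="stable")
    frame = frame.iloc[:k]
    frame["vip_combined_rank"] = np.arange(1, len(frame) + 1)
    return MarkerPanel(stage="final", frame=frame, k=k)


def run_panel_cascade(lung_diff, plasma_diffs, lung: SampleTable,
                      plasma_day5: SampleTable, k: int = 7,
                      vip_threshold: float = 1.0, rule: str = "either",
                      r_min: float = 0.0) -> MarkerPanel:
    """The full selection cascade from per-tissue screens to the final
    k-marker panel."""
    lung_set = set(lung_diff.significant_ids)
    plasma_set = union_differential(plasma_diffs)
    inter = intersect_tissues(lung_set, plasma_set)
    screened = vip_screen(inter, lung, plasma_day5,
                          threshold=vip_threshold, rule=rule, min_keep=k)
    corr = cross_tissue_corr(lung, plasma_day5, screened.members)
    k_eff = min(k, len(screened.members))
    return select_panel(screened, corr, plasma_day5, k=k_eff, r_min=r_min)


# ---------------------------------------------------------------------------
# triage


def triage_map(dose_gy: float, mapping=None) -> str:
    """Dose in Gy -> injury class (configurable bijection)."""
    mapping = DEFAULT_TRIAGE_MAP if mapping is None else mapping
    d = float(dose_gy)
    if d not in mapping:
        raise ValueError(f"dose {dose_gy} Gy not in the configured set "
                         f"{sorted(mapping)}")
    return mapping[d]


@dataclass
class TriageResult:
    """Cross-validated classification of injury severity for one day."""

    day: int
    classes: list
    per_sample: pd.DataFrame   # true_class, predicted_class, predicted_dose
    confusion: pd.DataFrame    # true x predicted counts
    cv_scheme: str = "loo"

    @property
    def per_class_accuracy(self) -> dict:
        acc = {}
        for c in self.classes:
            total = self.confusion.loc[c].sum()
            acc[c] = float(self.confusion.loc[c, c] / total) if total else \
                np.nan
        return acc

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion.to_numpy())
                     / self.confusion.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        return self.per_sample

    def to_dict(self) -> dict:
        return {"day": self.day, "cv_scheme": self.cv_scheme,
                "classes": list(self.classes),
                "confusion": self.confusion.to_dict(orient="index"),
                "per_class_accuracy": self.per_class_accuracy,
                "overall_accuracy": self.overall_accuracy,
                "per_sample": self.per_sample.to_dict(orient="index")}


def triage_evaluate(plasma_day: SampleTable, panel_metabolites,
                    n_osc: int = 1, n_components: int = 2,
                    cv: str = "loo", folds: int = 7, seed: int = 0,
                    gamma: float = None, mapping=None,
                    day: int = None) -> TriageResult:
    """Evaluate a marker panel as an OSC-KPLS severity classifier.

    Per held-out fold: unit-variance scaling, OSC filter and Gaussian
    KPLS (one-hot class response) are fit on the training fold only and
    applied to the held-out samples; predicted class is the argmax of
    the predicted indicators. A parallel KPLS on dose in Gy yields a
    continuous dose prediction. ``cv`` is ``loo`` (default), ``kfold``,
    or ``fitted`` for the apparent training-set accuracy (the scheme is
    recorded on the result so the two are never conflated).
    """
    mapping = DEFAULT_TRIAGE_MAP if mapping is None else mapping
    panel_metabolites = [m for m in panel_metabolites
                         if m in plasma_day.abundance.columns]
    if len(panel_metabolites) < 2:
        raise ValueError("panel must contain >= 2 metabolites present in "
                         "the table")
    sel = plasma_day.study_mask()
    sids = plasma_day.abundance.index[sel].tolist()
    X, _ = impute_mean(
        plasma_day.abundance.loc[sel, panel_metabolites].to_numpy(float))
    doses = plasma_day.samples.loc[sel, "dose_gy"].to_numpy(float)
    true_cls = [triage_map(d, mapping) for d in doses]
    classes = [c for c in TRIAGE_CLASSES if c in set(true_cls)] or \
        sorted(set(true_cls))
    n = X.shape[0]
    if cv == "fitted":
        # training-set (apparent) accuracy: fit once on everything
        assign = np.full(n, -1)
        n_folds = 1
    elif cv == "loo":
        assign = np.arange(n)
        n_folds = n
    elif cv == "kfold":
        order = np.random.default_rng(seed).permutation(n)
        assign = np.empty(n, dtype=int)
        assign[order] = np.arange(n) % folds
        n_folds = folds
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    pred_cls = np.empty(n, dtype=object)
    pred_dose = np.empty(n)
    for f in range(n_folds):
        if cv == "fitted":
            test = np.ones(n, dtype=bool)
            train = np.ones(n, dtype=bool)
        else:
            test = assign == f
            train = ~test
        if train.sum() < 3:
            raise ValueError("training fold too small")
        Xs_tr, center, sc = scale_matrix(X[train], "uv")
        Xs_te = (X[test] - center) / sc
        Y_cls = np.zeros((train.sum(), len(classes)))
        for i, c in enumerate(np.asarray(true_cls, dtype=object)[train]):
            Y_cls[i, classes.index(c)] = 1.0
        osc = osc_filter(Xs_tr, Y_cls, n_osc=n_osc)
        Xf_tr = osc.X_filtered
        Xf_te = osc.apply(Xs_te)
        ncomp = min(n_components, Xf_tr.shape[1], train.sum() - 1)
        km = KPLSModel(Xf_tr, Y_cls, kernel="gaussian", gamma=gamma,
                       scale="center_only").fit(ncomp)
        idx = np.argmax(km.predict(Xf_te), axis=1)
        pred_cls[test] = [classes[j] for j in idx]
        kd = KPLSModel(Xf_tr, doses[train], kernel="gaussian", gamma=gamma,
                       scale="center_only").fit(ncomp)
        pred_dose[test] = kd.predict(Xf_te)[:, 0]

    per_sample = pd.DataFrame({"true_class": true_cls,
                               "predicted_class": pred_cls,
                               "dose_gy": doses,
                               "predicted_dose_gy": pred_dose},
                              index=pd.Index(sids, name="sample_id"))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true_cls, pred_cls):
        conf.loc[t, p] += 1
    if day is None:
        dayvals = plasma_day.samples.loc[sel, "day"].dropna().unique()
        day = int(dayvals[0]) if len(dayvals) else -1
    return TriageResult(day=day, classes=classes, per_sample=per_sample,
                        confusion=conf, cv_scheme=cv)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectoryTable:
    """Ratio-to-control trajectories per metabolite and dose."""

    frame: pd.DataFrame  # MultiIndex (metabolite, dose); columns ratio_d<day>..., first_significant_day, monotone_2_to_5, direction
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.frame


def trajectories(plasma_by_day: dict, metabolites, diff_by_day: dict,
                 control_dose: float = 0.0,
                 direction_tol: float = 1e-9) -> TrajectoryTable:
    """Per metabolite and dose: mean irradiated level divided by mean
    control level at each day; the earliest day the metabolite was
    flagged significant; and whether the ratio moves monotonically
    (constant sign of successive changes) over the days >= 2."""
    days = sorted(plasma_by_day)
    if len(days) < 2:
        raise ValueError("need >= 2 days of plasma data")
    notes = []
    rows = {}
    doses = sorted(set().union(*[
        plasma_by_day[d].samples.loc[plasma_by_day[d].study_mask(),
                                     "dose_gy"].dropna().unique()
        for d in days]))
    doses = [d for d in doses if d != control_dose]
    for m in metabolites:
        first_sig = None
        for d in days:
            diff = diff_by_day.get(d)
            if diff is not None and m in diff.frame.index \
                    and diff.frame.loc[m, "significant"]:
                first_sig = d
                break
        for dose in doses:
            ratios = {}
            for d in days:
                tab = plasma_by_day[d]
                if m not in tab.abundance.columns:
                    ratios[d] = np.nan
                    continue
                sm = tab.samples
                ctrl = tab.abundance.loc[
                    tab.study_mask() & (sm["dose_gy"] == control_dose),
                    m].dropna()
                irr = tab.abundance.loc[
                    tab.study_mask() & (sm["dose_gy"] == dose), m].dropna()
                if not len(ctrl) or ctrl.mean() == 0 or not len(irr):
                    ratios[d] = np.nan
                    notes.append(f"{m} dose {dose} day {d}: undefined ratio")
                else:
                    ratios[d] = float(irr.mean() / ctrl.mean())
            late = [ratios[d] for d in days if d >= 2
                    and np.isfinite(ratios.get(d, np.nan))]
            changes = np.sign(np.diff(late)) if len(late) >= 2 else []
            monotone = bool(len(changes) and np.all(changes == changes[0])
                            and changes[0] != 0)
            last = ratios[days[-1]]
            if np.isfinite(last) and abs(np.log(last)) > direction_tol:
                direction = 1 if last > 1 else -1
            else:
                direction = 0
            row = {f"ratio_d{d}": ratios[d] for d in days}
            row.update({"first_significant_day": first_sig,
                        "monotone_2_to_5": monotone,
                        "direction": direction})
            rows[(m, dose)] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index = pd.MultiIndex.from_tuples(frame.index,
                                            names=["metabolite_id",
                                                   "dose_gy"])
    return TrajectoryTable(frame=frame, notes=notes)
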