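"""Differential-metabolite screening and fold-change zoning.

Univariate machinery for the dose-response screens: paired Wilcoxon
signed-rank (within-animal day contrasts), Mann-Whitney U (independent
control-vs-irradiated contrasts), one-way ANOVA across dose groups,
Benjamini-Hochberg FDR, and the clustered log2-fold-change "zone"
assignment used to summarize regulation patterns across doses.

A metabolite is called significant when its raw p-value is below
``alpha`` (default 0.05) AND its BH-adjusted q-value is below
``fdr_max`` (default 0.2); the BH family is all metabolites tested
within one contrast. Fold changes are ratios of arithmetic group means
on the normalized scale, missing values excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .datamodel import SampleTable


@dataclass
class DiffResult:
    """Per-metabolite statistics for one contrast."""

    contrast: str
    frame: pd.DataFrame  # index metabolite_id; statistic, p, q, log2fc, significant
    alpha: float = 0.05
    fdr_max: float = 0.2
    excluded: list = field(default_factory=list)

    @property
    def significant_ids(self) -> list:
        return self.frame.index[self.frame["significant"]].tolist()

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def to_dict(self) -> dict:
        return {"contrast": self.contrast, "alpha": self.alpha,
                "fdr_max": self.fdr_max, "excluded": self.excluded,
                "metabolites": self.frame.to_dict(orient="index")}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, contrast: str = "",
                   alpha: float = 0.05, fdr_max: float = 0.2) -> "DiffResult":
        return cls(contrast=contrast, frame=frame, alpha=alpha,
                   fdr_max=fdr_max)


def read_diff_result(path, contrast: str = "") -> DiffResult:
    """Re-import a CSV written by ``export_results``; numerics
    round-trip exactly (round-trip float parsing)."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return DiffResult.from_frame(frame, contrast=contrast)


@dataclass
class HeatmapZones:
    """Dose-wise log2 fold-change matrix with hierarchical-cluster zones."""

    log2fc_matrix: pd.DataFrame   # metabolite x dose
    metabolite_order: list        # dendrogram leaf order
    zone_labels: dict             # metabolite -> 'a' | 'b' | 'c' | ...


# ---------------------------------------------------------------------------
# elementary tests (scipy-backed, with the conventions fixed here)


def wilcoxon_signed_rank(x, y) -> tuple:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention). The returned
    statistic is W+ (sum of ranks of positive differences), so swapping
    x and y maps W to n(n+1)/2 - W. The null distribution is exact when
    the retained n <= 25 and |differences| are tie-free; otherwise a
    normal approximation with tie and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return w_plus, float(res.pvalue)


def mann_whitney_u(a, b) -> tuple:
    """Two-tailed Mann-Whitney U test for two independent samples.

    Exact null distribution when n_a + n_b <= 20 and the pooled sample
    is tie-free; otherwise normal approximation with tie correction and
    continuity correction. Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups) -> tuple:
    """Classical one-way fixed-effects ANOVA; F with (k-1, N-k) df.

    All-zero within-group variance with unequal means yields
    (F=inf, p=0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    means = [g.mean() for g in groups]
    if all(g.var() == 0 for g in groups):
        if np.ptp(means) > 0:
            return float("inf"), 0.0
        return 0.0, 1.0
    with np.errstate(invalid="ignore"):
        f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# screens


def _group_values(table: SampleTable, metabolite: str, doses) -> np.ndarray:
    sm = table.samples
    sel = table.study_mask() & sm["dose_gy"].isin(doses)
    vals = table.abundance.loc[sel, metabolite].dropna()
    return vals.to_numpy()


def differential_screen(table: SampleTable, test: str = "mann_whitney",
                        control_dose: float = 0.0, case_doses=None,
                        alpha: float = 0.05, fdr_max: float = 0.2,
                        min_n: int = 3) -> DiffResult:
    """Screen every metabolite of a filtered, normalized table.

    ``mann_whitney`` contrasts the control group against the pooled case
    doses (all non-control doses by default, or a supplied subset);
    ``anova`` tests across all dose groups. Metabolites with fewer than
    ``min_n`` observations in any group are excluded with a note. BH is
    applied across all metabolites actually tested in this contrast.
    """
    sm = table.samples
    all_doses = sorted(sm.loc[table.study_mask(), "dose_gy"].dropna()
                       .unique())
    if control_dose not in all_doses:
        raise ValueError(f"control dose {control_dose} absent from table")
    if case_doses is None:
        case_doses = [d for d in all_doses if d != control_dose]
    case_doses = list(case_doses)
    if not case_doses:
        raise ValueError("no case doses to contrast against control")

    rows, excluded = {}, []
    for m in table.measured_ids:
        ctrl = _group_values(table, m, [control_dose])
        if test == "anova":
            groups = [_group_values(table, m, [d])
                      for d in [control_dose] + case_doses]
            if any(g.size < min_n for g in groups):
                excluded.append(f"{m}: fewer than {min_n} observations in "
                                "a group")
                continue
            stat, p = anova_oneway(groups)
            case = np.concatenate(groups[1:])
        elif test == "mann_whitney":
            case = _group_values(table, m, case_doses)
            if ctrl.size < min_n or case.size < min_n:
                excluded.append(f"{m}: fewer than {min_n} observations in "
                                "a group")
                continue
            stat, p = mann_whitney_u(case, ctrl)
        else:
            raise ValueError(f"unknown test {test!r} for a between-group "
                             "screen")
        mc, mk = ctrl.mean(), case.mean()
        log2fc = np.log2(mk / mc) if mc > 0 and mk > 0 else np.nan
        rows[m] = {"statistic": stat, "p": p, "log2fc": log2fc}

    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "metabolite_id"
    if len(frame):
        frame["q"] = bh_fdr(frame["p"].to_numpy())
        frame["direction"] = np.sign(frame["log2fc"]).fillna(0).astype(int)
        frame["significant"] = (frame["p"] < alpha) & (frame["q"] < fdr_max)
        frame = frame[["statistic", "p", "q", "log2fc", "direction",
                       "significant"]]
    desc = (f"{test} dose {case_doses} vs control {control_dose}, "
            f"alpha={alpha}, fdr_max={fdr_max}")
    return DiffResult(contrast=desc, frame=frame, alpha=alpha,
                      fdr_max=fdr_max, excluded=excluded)


def paired_screen(table_a: SampleTable, table_b: SampleTable,
                  alpha: float = 0.05, fdr_max: float = 0.2,
                  min_n: int = 3) -> DiffResult:
    """Within-animal paired Wilcoxon screen between two tables (e.g. two
    plasma sampling days), pairing samples by ``animal_id``."""
    sa = table_a.samples.loc[table_a.study_mask()]
    sb = table_b.samples.loc[table_b.study_mask()]
    common = sorted(set(sa["animal_id"]) & set(sb["animal_id"]))
    if len(common) < min_n:
        raise ValueError("fewer than 3 animals shared between tables")
    ia = sa.index[sa["animal_id"].isin(common)]
    ib = sb.index[sb["animal_id"].isin(common)]
    a_of = table_a.abundance.loc[ia].set_axis(
        sa.loc[ia, "animal_id"], axis=0).sort_index()
    b_of = table_b.abundance.loc[ib].set_axis(
        sb.loc[ib, "animal_id"], axis=0).sort_index()

    rows, excluded = {}, []
    for m in table_a.measured_ids:
        if m not in b_of.columns:
            excluded.append(f"{m}: absent from second table")
            continue
        pair = pd.concat([a_of[m], b_of[m]], axis=1, keys=["a", "b"]).dropna()
        if len(pair) < min_n:
            excluded.append(f"{m}: fewer than {min_n} complete pairs")
            continue
        try:
            stat, p = wilcoxon_signed_rank(pair["a"], pair["b"])
        except ValueError:
            excluded.append(f"{m}: degenerate pairing")
            continue
        mb, ma = pair["b"].mean(), pair["a"].mean()
        log2fc = np.log2(ma / mb) if ma > 0 and mb > 0 else np.nan
        rows[m] = {"statistic": stat, "p": p, "log2fc": log2fc}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "metabolite_id"
    if len(frame):
        frame["q"] = bh_fdr(frame["p"].to_numpy())
        frame["direction"] = np.sign(frame["log2fc"]).fillna(0).astype(int)
        frame["significant"] = (frame["p"] < alpha) & (frame["q"] < fdr_max)
        frame = frame[["statistic", "p", "q", "log2fc", "direction",
                       "significant"]]
    return DiffResult(contrast="wilcoxon_paired a-vs-b by animal",
                      frame=frame, alpha=alpha, fdr_max=fdr_max,
                      excluded=excluded)


# ---------------------------------------------------------------------------
# fold-change zones


def log2fc_by_dose(table: SampleTable, metabolites,
                   control_dose: float = 0.0) -> pd.DataFrame:
    """Metabolite x dose matrix of log2(mean dose group / mean control)."""
    sm = table.samples
    doses = sorted(sm.loc[table.study_mask(), "dose_gy"].dropna().unique())
    doses = [d for d in doses if d != control_dose]
    out = {}
    for d in doses:
        col = {}
        for m in metabolites:
            ctrl = _group_values(table, m, [control_dose])
            case = _group_values(table, m, [d])
            col[m] = (np.log2(case.mean() / ctrl.mean())
                      if ctrl.size and case.size and ctrl.mean() > 0
                      and case.mean() > 0 else np.nan)
        out[d] = col
    mat = pd.DataFrame(out)
    mat.index.name = "metabolite_id"
    return mat


def heatmap_zones(diff: DiffResult, table: SampleTable, k: int = 3,
                  control_dose: float = 0.0) -> HeatmapZones:
    """Cluster significant metabolites on their dose-wise log2
    fold-change rows (Euclidean distance, average linkage) and cut the
    tree into ``k`` zones labelled 'a', 'b', ... in dendrogram-leaf
    order. Deterministic for fixed input."""
    sig = diff.significant_ids
    if len(sig) < k:
        raise ValueError(f"need >= {k} significant metabolites, have "
                         f"{len(sig)}")
    mat = log2fc_by_dose(table, sig, control_dose=control_dose).fillna(0.0)
    Z = hierarchy.linkage(mat.to_numpy(), method="average",
                          metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    order = [mat.index[i] for i in leaves]
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters in order of first appearance along the leaves
    seen, letters = {}, "abcdefghijklmnopqrstuvwxyz"
    for i in leaves:
        c = flat[i]
        if c not in seen:
            seen[c] = letters[len(seen)]
    zones = {mat.index[i]: seen[flat[i]] for i in range(len(flat))}
    return HeatmapZones(log2fc_matrix=mat.loc[order], metabolite_order=order,
                        zone_labels=zones)


def plot_heatmap_zones(zones: HeatmapZones, path) -> None:
    """Presentation-only clustered fold-change heatmap (PNG/PDF by file
    extension); rows in dendrogram order, zone letters on the right."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = zones.log2fc_matrix
    fig, ax = plt.subplots(
        figsize=(4 + 0.4 * mat.shape[1], 1 + 0.22 * mat.shape[0]))
    vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(mat.shape[1]),
                  [f"{d:g} Gy" for d in mat.columns])
    ax.set_yticks(range(mat.shape[0]), mat.index)
    for i, m in enumerate(mat.index):
        ax.text(mat.shape[1] - 0.4, i, zones.zone_labels[m],
                va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="log2 fold change vs control")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
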