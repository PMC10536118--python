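"""Carnitine palmitoyltransferase (CPT) surrogate ratios from
acylcarnitine channels, with group statistics.

The two surrogate activity indices are computed per sample from the
acyl-chain-annotated channels::

    CPT1 ratio = carnitine / (AC16:1 + AC18:0)
    CPT2 ratio = (AC16:0 + AC18:1) / AC2

A falling CPT1 ratio with rising CPT2 ratio after irradiation indicates
increased mitochondrial entry of long-chain acylcarnitines with
incomplete beta-oxidation. Group comparison uses the tie-corrected
Kruskal-Wallis test across all dose groups plus pairwise Mann-Whitney
tests of each dose against control and against the lowest irradiated
dose, with the conventional star marks (* p<0.05, ** p<0.01,
*** p<0.001; # vs 10 Gy). Quartiles use the linear-interpolation
(type-7) rule. Both ratios are invariant to any per-sample scaling, so
internal-standard normalization constants cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import SampleTable
from .stats import mann_whitney_u

CPT1_NUM = ("carnitine",)
CPT1_DEN = ("C16:1", "C18:0")
CPT2_NUM = ("C16:0", "C18:1")
CPT2_DEN = ("C2",)
REQUIRED_CHAINS = CPT1_NUM + CPT1_DEN + CPT2_NUM + CPT2_DEN


@dataclass
class RatioResult:
    per_sample: pd.DataFrame            # dose_gy, cpt1, cpt2
    group_stats: pd.DataFrame = None    # (ratio, dose): n, median, q25, q75
    kw_p: dict = field(default_factory=dict)
    pairwise: pd.DataFrame = None       # (ratio, dose, reference): p, stars
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.per_sample

    def to_dict(self) -> dict:
        d = {"per_sample": self.per_sample.to_dict(orient="index"),
             "kw_p": self.kw_p, "notes": self.notes}
        if self.group_stats is not None:
            d["group_stats"] = {str(k): v for k, v in
                                self.group_stats.to_dict(orient="index")
                                .items()}
        if self.pairwise is not None:
            d["pairwise"] = {str(k): v for k, v in
                             self.pairwise.to_dict(orient="index").items()}
        return d

    def summary_table(self) -> pd.DataFrame:
        """Ratios x dose groups, cells 'median (q25-q75)' with
        significance marks."""
        if self.group_stats is None:
            raise ValueError("run ratio_group_test first")
        out = {}
        for (ratio, dose), row in self.group_stats.iterrows():
            marks = ""
            if self.pairwise is not None:
                for (r2, d2, ref), prow in self.pairwise.iterrows():
                    if r2 == ratio and d2 == dose:
                        marks += prow["stars"]
            out.setdefault(ratio, {})[dose] = (
                f"{row['median']:.4g} {marks}".strip()
                + f" ({row['q25']:.4g}-{row['q75']:.4g})")
        return pd.DataFrame(out).T


def _chain_column(table: SampleTable, chain: str) -> str:
    mm = table.metabolites
    hits = mm.index[(mm["acyl_chain"] == chain)].tolist()
    if not hits:
        return None
    return hits[0]


def cpt_ratios(table: SampleTable) -> RatioResult:
    """Per-sample CPT1/CPT2 surrogate ratios over study samples.

    A sample whose constituent channel is missing, or whose denominator
    is zero, gets a missing ratio with a note.
    """
    cols = {c: _chain_column(table, c) for c in REQUIRED_CHAINS}
    absent = [c for c, col in cols.items() if col is None]
    if absent:
        raise ValueError("table lacks acyl-chain channels required for the "
                         f"CPT ratios: {absent}")
    sel = table.study_mask()
    ab = table.abundance.loc[sel]
    doses = table.samples.loc[sel, "dose_gy"]
    notes = []
    rows = {}
    for sid in ab.index:
        vals = {c: ab.loc[sid, cols[c]] for c in REQUIRED_CHAINS}
        cpt1 = cpt2 = np.nan
        if any(pd.isna(vals[c]) for c in CPT1_NUM + CPT1_DEN):
            notes.append(f"{sid}: missing constituent for CPT1")
        else:
            den = sum(vals[c] for c in CPT1_DEN)
            if den == 0:
                notes.append(f"{sid}: zero denominator for CPT1")
            else:
                cpt1 = vals["carnitine"] / den
        if any(pd.isna(vals[c]) for c in CPT2_NUM + CPT2_DEN):
            notes.append(f"{sid}: missing constituent for CPT2")
        else:
            den = vals["C2"]
            if den == 0:
                notes.append(f"{sid}: zero denominator for CPT2")
            else:
                cpt2 = sum(vals[c] for c in CPT2_NUM) / den
        rows[sid] = {"dose_gy": float(doses[sid]), "cpt1": cpt1,
                     "cpt2": cpt2}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return RatioResult(per_sample=frame, notes=notes)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ratio_group_test(result: RatioResult, control_dose: float = 0.0,
                     reference_dose: float = None,
                     min_n: int = 3) -> RatioResult:
    """Complete a RatioResult with group medians/quartiles, the
    Kruskal-Wallis p across all dose groups and pairwise Mann-Whitney
    tests vs control (stars) and vs the lowest irradiated dose (#)."""
    frame = result.per_sample
    doses = sorted(frame["dose_gy"].dropna().unique())
    if reference_dose is None:
        irr = [d for d in doses if d != control_dose]
        reference_dose = irr[0] if irr else None
    stats_rows = {}
    pair_rows = {}
    for ratio in ("cpt1", "cpt2"):
        groups, used_doses = [], []
        for d in doses:
            vals = frame.loc[frame["dose_gy"] == d, ratio].dropna() \
                .to_numpy()
            if len(vals) < min_n:
                result.notes.append(f"{ratio}: dose {d} has fewer than "
                                    f"{min_n} samples, excluded from tests")
                continue
            groups.append(vals)
            used_doses.append(d)
            stats_rows[(ratio, d)] = {
                "n": len(vals),
                "median": float(np.quantile(vals, 0.5)),
                "q25": float(np.quantile(vals, 0.25)),
                "q75": float(np.quantile(vals, 0.75))}
        if len(groups) >= 2:
            if all(np.array_equal(g, groups[0]) for g in groups[1:]):
                result.kw_p[ratio] = 1.0
            else:
                _, p = sps.kruskal(*groups)
                result.kw_p[ratio] = float(p)
        ctrl = dict(zip(used_doses, groups)).get(control_dose)
        ref = dict(zip(used_doses, groups)).get(reference_dose)
        for d, g in zip(used_doses, groups):
            if ctrl is not None and d != control_dose:
                _, p = mann_whitney_u(g, ctrl)
                pair_rows[(ratio, d, control_dose)] = {
                    "p": p, "stars": _stars(p)}
            if ref is not None and d not in (control_dose, reference_dose):
                _, p = mann_whitney_u(g, ref)
                pair_rows[(ratio, d, reference_dose)] = {
                    "p": p, "stars": "#" if p < 0.05 else ""}
    gs = pd.DataFrame.from_dict(stats_rows, orient="index")
    gs.index = pd.MultiIndex.from_tuples(gs.index, names=["ratio", "dose_gy"])
    result.group_stats = gs
    if pair_rows:
        pw = pd.DataFrame.from_dict(pair_rows, orient="index")
        pw.index = pd.MultiIndex.from_tuples(
            pw.index, names=["ratio", "dose_gy", "reference"])
        result.pairwise = pw
    return result
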