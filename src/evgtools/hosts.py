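"""Host-group prediction from genome-wide similarity, and gene colinearity.

For every labelled reference genome with at least one same-group and one
different-group partner, the best S_G toward each partner class is recorded
(two scores per eligible genome). Sliding the cutoff over these scores gives
a precision curve, from which an operating cutoff with a target precision is
chosen; unlabelled genomes then inherit the host group of their best-scoring
labelled partner when that S_G exceeds the cutoff. Gene-level colinearity
B_g is the percentage of a genome's genes with bidirectional-best-hit
protein orthologs in a partner genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import HSP, find_hsps


# ---------------------------------------------------------------------------
# score recording and precision
# ---------------------------------------------------------------------------

def record_best_scores(sg: pd.DataFrame, host_labels: dict[str, str]) -> pd.DataFrame:
    """Best same-group and best different-group S_G per eligible genome.

    A labelled genome is eligible when it has at least one labelled partner
    inside and one outside its host group; ineligible genomes are excluded
    with a warning. The output holds exactly two scores per eligible genome.
    """
    labeled = [g for g in sg.index if g in host_labels]
    rows = []
    skipped = []
    for g in labeled:
        group = host_labels[g]
        same = [h for h in labeled if h != g and host_labels[h] == group]
        diff = [h for h in labeled if h != g and host_labels[h] != group]
        if not same or not diff:
            skipped.append(g)
            continue
        rows.append(
            {
                "genome_id": g,
                "host_group": group,
                "best_same_group_sg": float(sg.loc[g, same].max()),
                "best_diff_group_sg": float(sg.loc[g, diff].max()),
            }
        )
    if skipped:
        warnings.warn(f"{len(skipped)} genomes without eligible partners excluded")
    return pd.DataFrame(rows)


@dataclass
class PrecisionCurve:
    cutoffs: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    precision: np.ndarray  # NaN where TP + FP = 0


def precision_curve(records: pd.DataFrame, grid: np.ndarray | None = None) -> PrecisionCurve:
    """Precision of 'same host group' over sliding S_G cutoffs.

    At cutoff t: TP = same-group scores > t, FP = different-group scores > t.
    The default grid slides in 0.0001 steps over the observed score range.
    """
    if records.empty:
        raise ValueError("no score records")
    same = records["best_same_group_sg"].to_numpy()
    diff = records["best_diff_group_sg"].to_numpy()
    if grid is None:
        lo = 0.0
        hi = float(max(same.max(), diff.max()))
        grid = np.round(np.arange(lo, hi + 1e-4, 1e-4), 4)
    tp = np.array([(same > t).sum() for t in grid])
    fp = np.array([(diff > t).sum() for t in grid])
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
    return PrecisionCurve(np.asarray(grid, dtype=float), tp, fp, prec)


def choose_cutoff(curve: PrecisionCurve, target_precision: float) -> float | None:
    """Smallest cutoff with precision above target that stays above target
    at every larger cutoff where precision is defined; None if never met."""
    ok = curve.precision > target_precision  # NaN compares False
    defined = ~np.isnan(curve.precision)
    for i in range(len(curve.cutoffs)):
        if ok[i] and np.all(ok[i:] | ~defined[i:]):
            return float(curve.cutoffs[i])
    return None


def predict_hosts(
    sg: pd.DataFrame,
    host_labels: dict[str, str],
    unlabeled: list[str],
    cutoff: float,
) -> pd.DataFrame:
    """Assign each unlabelled genome its best labelled partner's host group
    iff that best S_G strictly exceeds the cutoff."""
    labeled = [g for g in sg.index if g in host_labels]
    columns = ["genome_id", "best_partner", "best_sg", "predicted_host_group", "predicted"]
    if not unlabeled:
        return pd.DataFrame(columns=columns)
    rows = []
    for g in unlabeled:
        scores = sg.loc[g, labeled]
        best_partner = scores.idxmax()
        best = float(scores.loc[best_partner])
        predicted = best > cutoff
        rows.append(
            {
                "genome_id": g,
                "best_partner": best_partner,
                "best_sg": best,
                "predicted_host_group": host_labels[best_partner] if predicted else None,
                "predicted": predicted,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bidirectional best hits / colinearity
# ---------------------------------------------------------------------------

@dataclass
class OrthologMap:
    pairs: dict[str, str]  # gene in A -> gene in B
    b_g: float  # % of A's genes with an ortholog

    def inverse(self) -> dict[str, str]:
        return {v: k for k, v in self.pairs.items()}


def _best_hits(hsps: list[HSP], evalue_max: float) -> dict[str, str]:
    """Best subject per query by bit score; ties by longer alignment then
    lexicographic subject id."""
    best: dict[str, HSP] = {}
    for h in hsps:
        if h.evalue >= evalue_max or h.query == h.subject:
            continue
        cur = best.get(h.query)
        if cur is None or (-h.bitscore, -h.length, h.subject) < (-cur.bitscore, -cur.length, cur.subject):
            best[h.query] = h
    return {q: h.subject for q, h in best.items()}


def bidirectional_best_hits(
    genes_a: dict[str, str],
    genes_b: dict[str, str],
    evalue_max: float = 1e-5,
    hsps_ab: list[HSP] | None = None,
    hsps_ba: list[HSP] | None = None,
) -> OrthologMap:
    """One-to-one orthologs by mutual best protein hits (E < ``evalue_max``).

    ``genes_a``/``genes_b`` map gene ids to protein sequences; precomputed
    HSP lists may be supplied to skip the searches. B_g is the percentage of
    A's genes with an ortholog.
    """
    if not genes_a:
        raise ValueError("genome A has no genes; B_g undefined")
    if hsps_ab is None:
        hsps_ab = find_hsps(genes_a, genes_b, mode="protein", evalue=evalue_max)
    if hsps_ba is None:
        hsps_ba = find_hsps(genes_b, genes_a, mode="protein", evalue=evalue_max)
    ab = _best_hits(hsps_ab, evalue_max)
    ba = _best_hits(hsps_ba, evalue_max)
    pairs = {qa: sb for qa, sb in ab.items() if ba.get(sb) == qa}
    return OrthologMap(pairs, 100.0 * len(pairs) / len(genes_a))


def is_nearly_colinear(ortholog_map: OrthologMap, min_bg: float = 60.0) -> bool:
    """Nearly complete genomic colinearity: B_g of at least 60%."""
    return ortholog_map.b_g >= min_bg
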