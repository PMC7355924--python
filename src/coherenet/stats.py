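"""Per-class ratio tables and two-proportion tests.

For every subgraph class (Act, Inh, the dual and multi-edge loop classes,
and the UGP null) the classified pairs are tallied into positive /
negative / non-significant counts — plus coherent / incoherent for the
simple Act and Inh classes where an edge sign fixes the expectation.
Class proportions are then compared pairwise with the pooled two-sample
z-test ("binomial proportion test"), BH-adjusted across the comparison
family.

The UGP row averages proportions over replicates (its counts are pooled;
with equal replicate sizes the two coincide), and pairwise tests use the
pooled counts.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import PairAssociation, classify_edge_coherency, fdr_adjust
from .census import SUBGRAPH_CLASSES, SubgraphAssignment

COUNT_COLS = ("n_total", "n_positive", "n_negative", "n_nonsig",
              "n_coherent", "n_incoherent")


@dataclass
class ProportionTestResult:
    """Pooled two-sample z-test between two class proportions."""

    class_a: str
    class_b: str
    proportion: str
    k1: int
    n1: int
    k2: int
    n2: int
    z: float
    p: float
    q: float | None = None


@dataclass
class RatioTable:
    """Per-class category counts and proportions.

    ``table`` has one row per subgraph class; ``ugp_replicates`` keeps the
    per-replicate UGP counts behind the averaged UGP row.  Rows with no
    classified pairs are flagged ``empty``.
    """

    table: pd.DataFrame
    ugp_replicates: pd.DataFrame

    def counts(self, label: str) -> dict[str, int]:
        row = self.table.loc[label]
        return {c: int(row[c]) for c in COUNT_COLS if not pd.isna(row[c])}


def _tally(categories, coherencies=None) -> dict:
    cats = list(categories)
    row = {
        "n_total": len(cats),
        "n_positive": sum(c == "positive" for c in cats),
        "n_negative": sum(c == "negative" for c in cats),
        "n_nonsig": sum(c == "non_significant" for c in cats),
        "n_coherent": np.nan,
        "n_incoherent": np.nan,
    }
    if coherencies is not None:
        coh = list(coherencies)
        row["n_coherent"] = sum(c == "coherent" for c in coh)
        row["n_incoherent"] = sum(c == "incoherent" for c in coh)
    return row


def _proportions(row: dict) -> dict:
    n = row["n_total"]
    for cat in ("positive", "negative", "nonsig"):
        row[f"p_{cat}"] = row[f"n_{cat}"] / n if n else np.nan
    return row


def build_ratio_table(
    associations: dict[tuple[str, str], PairAssociation],
    assignments: list[SubgraphAssignment],
    edge_signs: dict[tuple[str, str], int],
    ugp_categories: dict[int, list[str]] | None = None,
) -> RatioTable:
    """Tally sign categories per subgraph class.

    ``associations`` maps ordered gene pairs to classified associations
    (homogeneous eligible pairs only — exactly the pairs whose category is
    defined).  ``assignments`` come from the dual/multi census; classes
    overlap by design, so each class is tallied independently.
    ``ugp_categories`` maps replicate index to that replicate's category
    list.
    """

    def lookup(a: str, b: str) -> str | None:
        assoc = associations.get((a, b)) or associations.get((b, a))
        return assoc.category if assoc is not None else None

    rows: dict[str, dict] = {}

    # simple classes from direct edges
    for label, want in (("Act", 1), ("Inh", -1)):
        cats, cohs = [], []
        for (src, tgt), sign in sorted(edge_signs.items()):
            if sign != want:
                continue
            cat = lookup(src, tgt)
            if cat is None:
                continue
            cats.append(cat)
            cohs.append(classify_edge_coherency(sign, cat).call)
        rows[label] = _tally(cats, cohs)

    # dual and multi classes from census assignments
    by_class: dict[str, list[str]] = {}
    for a in assignments:
        if a.label is None:
            continue
        cat = lookup(a.gene_i, a.gene_j)
        if cat is None:
            continue
        by_class.setdefault(a.label, []).append(cat)
    for label in SUBGRAPH_CLASSES:
        if label in ("UGP", "Act", "Inh"):
            continue
        rows[label] = _tally(by_class.get(label, []))

    # UGP: pooled counts, averaged proportions, per-replicate audit
    rep_rows = []
    if ugp_categories:
        pooled: list[str] = []
        for rep in sorted(ugp_categories):
            cats = ugp_categories[rep]
            pooled.extend(cats)
            rep_rows.append({"replicate": rep, **_proportions(_tally(cats))})
        row = _tally(pooled)
        reps = pd.DataFrame(rep_rows)
        row["p_positive"] = float(reps["p_positive"].mean())
        row["p_negative"] = float(reps["p_negative"].mean())
        row["p_nonsig"] = float(reps["p_nonsig"].mean())
        rows["UGP"] = row
    else:
        rows["UGP"] = _tally([])

    for label, row in rows.items():
        if "p_positive" not in row:
            _proportions(row)
        row["empty"] = row["n_total"] == 0

    table = pd.DataFrame.from_dict(rows, orient="index").reindex(list(SUBGRAPH_CLASSES))
    table.index.name = "class"
    rep_df = pd.DataFrame(rep_rows) if rep_rows else pd.DataFrame(
        columns=["replicate", *COUNT_COLS])
    return RatioTable(table, rep_df)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int,
                        continuity: bool = False) -> ProportionTestResult:
    """Pooled two-sample z-test for equality of two proportions.

    z = (p1 - p2) / sqrt(p̂ (1-p̂) (1/n1 + 1/n2)) with p̂ pooled; the
    two-sided p comes from the normal tail.  No continuity correction by
    default (``continuity=True`` applies the prop.test-style half-unit
    correction).  Degenerate pooled proportions (0 or 1, which force
    p1 == p2) give z = 0, p = 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError(f"invalid counts k={k}, n={n}")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult("", "", "", k1, n1, k2, n2, 0.0, 1.0)
    d = p1 - p2
    if continuity:
        cc = 0.5 * (1 / n1 + 1 / n2)
        d = math.copysign(max(abs(d) - cc, 0.0), d)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = d / se
    p = 2 * sps.norm.sf(abs(z))
    return ProportionTestResult("", "", "", k1, n1, k2, n2, float(z), float(p))


def compare_all_classes(
    table: RatioTable,
    proportion: str = "positive",
    continuity: bool = False,
) -> pd.DataFrame:
    """All pairwise class comparisons of one proportion, BH-adjusted.

    ``proportion`` is one of positive / negative / coherent (coherent only
    involves Act and Inh).  Classes with no classified pairs are skipped.
    The UGP row enters with its pooled counts.
    """
    col = {"positive": "n_positive", "negative": "n_negative",
           "coherent": "n_coherent"}[proportion]
    tab = table.table
    usable = [
        label for label in tab.index
        if tab.loc[label, "n_total"] > 0 and not pd.isna(tab.loc[label, col])
    ]
    if len(usable) < 2:
        raise ValueError("need >= 2 non-empty classes to compare")
    results = []
    for a, b in itertools.combinations(usable, 2):
        res = two_proportion_test(
            int(tab.loc[a, col]), int(tab.loc[a, "n_total"]),
            int(tab.loc[b, col]), int(tab.loc[b, "n_total"]),
            continuity=continuity)
        res.class_a, res.class_b, res.proportion = a, b, proportion
        results.append(res)
    qs = fdr_adjust([res.p for res in results])
    for res, q in zip(results, qs):
        res.q = float(q)
    return pd.DataFrame([{
        "class_a": r.class_a, "class_b": r.class_b, "proportion": r.proportion,
        "k1": r.k1, "n1": r.n1, "k2": r.k2, "n2": r.n2,
        "z": r.z, "p": r.p, "q": r.q,
    } for r in results])
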