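"""End-to-end orchestration: network load -> eligibility -> correlation /
homogeneity -> FDR -> classification -> census -> UGP null -> ratio table
-> proportion tests.

Every stage drops records for auditable reasons (self-loops, ambiguous
signs, ineligible pairs, heterogeneous pairs, constant vectors); the run
summary keeps the counts so the filter funnel is conserved exactly:

    n_edges == n_ineligible + n_heterogeneous
               + (n_positive + n_negative + n_non_significant)

Runs are idempotent for a fixed config and seed: output tables are sorted
and written with fixed float formatting, so re-runs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (IneligiblePairError, PairAssociation, assess_pair,
                          classify_deg_coherency, classify_edge_coherency,
                          classify_sign_category, fdr_adjust)
from .census import (SubgraphAssignment, UGPSet, census_dual, census_multi,
                     sample_ugp)
from .expression import ExpressionCollection, read_deg_labels, read_manifest
from .network import (NetworkMetrics, SignedNetwork, merge_edge_lists,
                      read_edge_list)
from .stats import RatioTable, build_ratio_table, compare_all_classes

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Every policy the method leaves open is an explicit key: the
    correlation method, the per-dataset aggregation, the sign-conflict
    policy at merge time, and the tested proportion for the class
    comparisons.
    """

    edge_lists: list[str]
    manifest: str
    method: str = "pearson"
    min_n: int = 3
    alpha: float = 0.05
    aggregation: str = "weighted_mean"
    conflict_policy: str = "ambiguous"
    ugp_m: int = 1000
    ugp_replicates: int = 10
    seed: int = 0
    log2: bool = False
    deg_labels: str | None = None
    compare_proportion: str = "positive"
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        # resolve paths relative to the config file
        cfg.edge_lists = [str(_resolve(p, path.parent)) for p in cfg.edge_lists]
        cfg.manifest = str(_resolve(cfg.manifest, path.parent))
        if cfg.deg_labels:
            cfg.deg_labels = str(_resolve(cfg.deg_labels, path.parent))
        if cfg.outdir:
            cfg.outdir = str(_resolve(cfg.outdir, path.parent))
        return cfg


def _resolve(p: str, base: Path) -> Path:
    q = Path(p)
    return q if q.is_absolute() else base / q


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    network: SignedNetwork
    giant: SignedNetwork
    metrics: NetworkMetrics
    pairs: pd.DataFrame
    census: list[SubgraphAssignment]
    ugp_sets: list[UGPSet]
    ugp_pairs: pd.DataFrame
    ratio_table: RatioTable
    proportion_tests: pd.DataFrame
    deg_calls: pd.DataFrame | None
    summary: dict


class Pipeline:
    """Lazy, stage-wise execution of one configured run.

    Stages are cached properties so CLI subcommands can ask for just the
    artifact they need; :meth:`run` materializes everything and writes
    the report bundle.
    """

    def __init__(self, cfg: RunConfig) -> None:
        self.cfg = cfg
        for p in [*cfg.edge_lists, cfg.manifest] + (
                [cfg.deg_labels] if cfg.deg_labels else []):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")

    # -- stage 1: network -------------------------------------------------
    @cached_property
    def network(self) -> SignedNetwork:
        lists = [read_edge_list(p) for p in self.cfg.edge_lists]
        return merge_edge_lists(lists, conflict_policy=self.cfg.conflict_policy)

    @cached_property
    def collection(self) -> ExpressionCollection:
        return read_manifest(self.cfg.manifest, log2=self.cfg.log2)

    # -- stage 2+3: eligibility, correlation, classification --------------
    @cached_property
    def pairs(self) -> pd.DataFrame:
        """Per-edge association table (the volcano/pie source data).

        One row per directed, unambiguous edge with its status:
        ``ineligible`` / ``heterogeneous`` / ``classified``.
        """
        cfg = self.cfg
        rows = []
        assocs: dict[tuple[str, str], PairAssociation] = {}
        for (src, tgt), sign in sorted(self.network.edge_signs.items()):
            row = {"gene_i": src, "gene_j": tgt, "edge_sign": sign,
                   "n_datasets": 0, "combined_r": np.nan, "combined_p": np.nan,
                   "q": np.nan, "homogeneous": False, "status": "ineligible",
                   "category": "", "coherency": ""}
            try:
                assoc = assess_pair(src, tgt, self.collection, method=cfg.method,
                                    min_n=cfg.min_n, aggregation=cfg.aggregation)
            except IneligiblePairError:
                rows.append(row)
                continue
            row.update(n_datasets=assoc.n_datasets, combined_r=assoc.combined_r,
                       combined_p=assoc.combined_p, homogeneous=assoc.homogeneous)
            if not assoc.homogeneous:
                row["status"] = "heterogeneous"
            else:
                row["status"] = "classified"
                assocs[(src, tgt)] = assoc
            rows.append(row)

        # one BH family over all homogeneous eligible edges of the run
        if assocs:
            keys = sorted(assocs)
            qs = fdr_adjust([assocs[k].combined_p for k in keys])
            for k, q in zip(keys, qs):
                assocs[k].q = float(q)
                assocs[k].category = classify_sign_category(assocs[k], cfg.alpha)
        for row in rows:
            key = (row["gene_i"], row["gene_j"])
            if key in assocs:
                assoc = assocs[key]
                row["q"] = assoc.q
                row["category"] = assoc.category
                row["coherency"] = classify_edge_coherency(
                    row["edge_sign"], assoc.category).call
        self._edge_assocs = assocs
        return pd.DataFrame(rows)

    @property
    def edge_associations(self) -> dict[tuple[str, str], PairAssociation]:
        self.pairs  # noqa: B018 — materializes the cache
        return self._edge_assocs

    # -- stage 4: census on the giant component of eligible edges ---------
    @cached_property
    def eligible_giant(self) -> SignedNetwork:
        df = self.pairs
        eligible = df[df["status"] != "ineligible"]
        keep = set(zip(eligible["gene_i"], eligible["gene_j"]))
        sub = SignedNetwork([e for e in self.network.edges if e.pair in keep])
        if not sub.nodes:
            raise ValueError("no eligible edges; cannot build giant component")
        return sub.giant_component()

    @cached_property
    def metrics(self) -> NetworkMetrics:
        return self.eligible_giant.metrics()

    @cached_property
    def census(self) -> list[SubgraphAssignment]:
        gc = self.eligible_giant
        return census_dual(gc) + census_multi(gc, max_len=self.metrics.radius)

    # -- stage 5: UGP null -------------------------------------------------
    @cached_property
    def ugp_sets(self) -> list[UGPSet]:
        return sample_ugp(self.eligible_giant, self.collection,
                          m=self.cfg.ugp_m, n_replicates=self.cfg.ugp_replicates,
                          seed=self.cfg.seed, min_n=self.cfg.min_n)

    @cached_property
    def ugp_pairs(self) -> pd.DataFrame:
        """Per-UGP-pair associations; one BH family per replicate."""
        cfg = self.cfg
        rows = []
        for us in self.ugp_sets:
            reps = []
            for a, b in us.pairs:
                try:
                    assoc = assess_pair(a, b, self.collection, method=cfg.method,
                                        min_n=cfg.min_n, aggregation=cfg.aggregation)
                except IneligiblePairError:
                    continue
                if assoc.homogeneous:
                    reps.append(assoc)
            if reps:
                qs = fdr_adjust([assoc.combined_p for assoc in reps])
                for assoc, q in zip(reps, qs):
                    assoc.q = float(q)
                    assoc.category = classify_sign_category(assoc, cfg.alpha)
            rows.extend({
                "replicate": us.replicate, "gene_i": assoc.gene_i,
                "gene_j": assoc.gene_j, "combined_r": assoc.combined_r,
                "combined_p": assoc.combined_p, "q": assoc.q,
                "category": assoc.category,
            } for assoc in reps)
        return pd.DataFrame(rows)

    # -- stage 6: ratios and proportion tests ------------------------------
    @cached_property
    def ratio_table(self) -> RatioTable:
        ugp_cats: dict[int, list[str]] = {}
        for rep, grp in self.ugp_pairs.groupby("replicate"):
            ugp_cats[int(rep)] = grp["category"].tolist()
        return build_ratio_table(self.edge_associations, self.census,
                                 self.network.edge_signs, ugp_cats)

    @cached_property
    def proportion_tests(self) -> pd.DataFrame:
        return compare_all_classes(self.ratio_table,
                                   proportion=self.cfg.compare_proportion)

    # -- optional DEG truth-table analysis ---------------------------------
    @cached_property
    def deg_calls(self) -> pd.DataFrame | None:
        if not self.cfg.deg_labels:
            return None
        labels = read_deg_labels(self.cfg.deg_labels)
        rows = []
        for (src, tgt), sign in sorted(self.network.edge_signs.items()):
            if src in labels and tgt in labels:
                rows.append({
                    "gene_i": src, "gene_j": tgt, "edge_sign": sign,
                    "dir_i": labels[src], "dir_j": labels[tgt],
                    "deg_coherency": classify_deg_coherency(
                        labels[src], labels[tgt], sign),
                })
        return pd.DataFrame(rows)

    # -- summary and report bundle -----------------------------------------
    def summary(self) -> dict:
        df = self.pairs
        counts = {
            "n_edges": int(len(df)),
            "n_ineligible": int((df["status"] == "ineligible").sum()),
            "n_heterogeneous": int((df["status"] == "heterogeneous").sum()),
            "n_classified": int((df["status"] == "classified").sum()),
            "n_positive": int((df["category"] == "positive").sum()),
            "n_negative": int((df["category"] == "negative").sum()),
            "n_non_significant": int((df["category"] == "non_significant").sum()),
            "n_coherent": int((df["coherency"] == "coherent").sum()),
            "n_incoherent": int((df["coherency"] == "incoherent").sum()),
        }
        n_eligible = counts["n_classified"] + counts["n_heterogeneous"]
        census_counts: dict[str, int] = {}
        for a in self.census:
            if a.label:
                census_counts[a.label] = census_counts.get(a.label, 0) + 1
        cfg_dict = dataclasses.asdict(self.cfg)
        cfg_dict.pop("outdir", None)   # run location, not an analysis input
        out = {
            "version": __version__,
            "config": cfg_dict,
            "network_audit": self.network.audit,
            "funnel": counts,
            "eligible_edge_ratio": n_eligible / counts["n_edges"] if counts["n_edges"] else None,
            "coherent_fraction_significant": (
                counts["n_coherent"] / (counts["n_coherent"] + counts["n_incoherent"])
                if counts["n_coherent"] + counts["n_incoherent"] else None),
            "giant_component": {
                "n_nodes": self.metrics.n_nodes,
                "diameter": self.metrics.diameter,
                "radius": self.metrics.radius,
            },
            "census_counts": dict(sorted(census_counts.items())),
            "ugp": {"m": self.cfg.ugp_m, "replicates": self.cfg.ugp_replicates,
                    "seed": self.cfg.seed},
        }
        if self.deg_calls is not None and len(self.deg_calls):
            dc = self.deg_calls["deg_coherency"]
            out["deg"] = {"n_labeled_edges": int(len(dc)),
                          "n_coherent": int((dc == "coherent").sum()),
                          "n_incoherent": int((dc == "incoherent").sum())}
        return out

    def run(self) -> PipelineResult:
        """Execute all stages; write the report bundle if outdir is set."""
        result = PipelineResult(
            network=self.network, giant=self.eligible_giant,
            metrics=self.metrics, pairs=self.pairs, census=self.census,
            ugp_sets=self.ugp_sets, ugp_pairs=self.ugp_pairs,
            ratio_table=self.ratio_table,
            proportion_tests=self.proportion_tests,
            deg_calls=self.deg_calls, summary=self.summary(),
        )
        if self.cfg.outdir:
            self.write(Path(self.cfg.outdir), result)
        return result

    def write(self, outdir: Path, result: PipelineResult) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        result.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FMT)
        census_df = pd.DataFrame([{
            "gene_i": a.gene_i, "gene_j": a.gene_j,
            "class": a.label or "excluded_mixed", "kind": a.kind,
            "s_direct": a.s_direct, "s_indirect": a.s_indirect,
            "k_star": "" if a.k is None else a.k,
        } for a in result.census])
        census_df.to_csv(outdir / "census.tsv", sep="\t", index=False)
        result.ugp_pairs.to_csv(outdir / "ugp_pairs.tsv", sep="\t", index=False,
                                float_format=_FLOAT_FMT)
        result.ratio_table.table.to_csv(outdir / "ratio_table.tsv", sep="\t",
                                        float_format=_FLOAT_FMT)
        result.ratio_table.ugp_replicates.to_csv(
            outdir / "ugp_replicates.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        result.proportion_tests.to_csv(outdir / "proportion_tests.tsv", sep="\t",
                                       index=False, float_format=_FLOAT_FMT)
        if result.deg_calls is not None:
            result.deg_calls.to_csv(outdir / "deg_coherency.tsv", sep="\t",
                                    index=False)
        with (outdir / "summary.json").open("w") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """One-call entry point: execute a configured run end to end."""
    return Pipeline(cfg).run()
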