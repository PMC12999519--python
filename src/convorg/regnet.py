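"""Module -> module regulatory scoring from regulator->target annotations.

The regulation score of an ordered module pair (U -> V) is the
kME-weighted proportion of V's genes annotated as targets of at least
one high-confidence regulator residing in U:

    score(U -> V) = sum over regulated genes g in V of kME_V(g) / |V|

Edges are the ordered pairs whose score strictly exceeds
mean + 1 * population SD over all ordered pairs with U != V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, ModuleSet


def load_annotation(annot: pd.DataFrame, universe, high_confidence_only: bool = True):
    """Harmonize an annotation table to the expression universe.

    Drops duplicate (regulator, target) pairs and pairs whose genes are
    outside the universe; returns ``(table, n_dropped)``.
    """
    df = annot.copy()
    if high_confidence_only and "high_confidence" in df.columns:
        df = df[df["high_confidence"].astype(bool)]
    before = len(df)
    df = df.drop_duplicates(subset=["regulator", "target"])
    uni = set(universe)
    df = df[df["regulator"].isin(uni) & df["target"].isin(uni)]
    return df.reset_index(drop=True), before - len(df)


def module_regulation_score(
    modules: ModuleSet, annot: pd.DataFrame, upstream: int, downstream: int
) -> float:
    """kME-weighted proportion of the downstream module regulated from upstream.

    Genes regulated by several upstream regulators are counted once;
    negative kME values enter the sum as-is.
    """
    if upstream == downstream:
        raise ValueError("upstream and downstream modules must differ")
    genes_u = set(modules.module_genes(upstream))
    genes_v = modules.module_genes(downstream)
    if len(genes_v) == 0:
        raise ValueError(f"module {downstream} is empty")
    regs_in_u = set(annot["regulator"]) & genes_u
    if not regs_in_u:
        return 0.0
    targets = set(annot.loc[annot["regulator"].isin(regs_in_u), "target"])
    regulated = [g for g in genes_v if g in targets]
    if not regulated:
        return 0.0
    return float(modules.kme.loc[regulated, f"M{downstream}"].sum() / len(genes_v))


@dataclass
class ModuleRegulationGraph:
    scores: pd.DataFrame  # columns: from, to, score, is_edge
    threshold: float
    warnings: list

    def edges(self) -> pd.DataFrame:
        return self.scores[self.scores["is_edge"]].reset_index(drop=True)

    def out_degree(self) -> pd.Series:
        return self.edges().groupby("from").size().rename("out_degree")

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for _, row in self.edges().iterrows():
            g.add_edge(f"M{int(row['from'])}", f"M{int(row['to'])}", score=float(row["score"]))
        nx.write_graphml(g, path)


def regulation_graph(
    modules: ModuleSet, annot: pd.DataFrame, population_sd: bool = True
) -> ModuleRegulationGraph:
    """Score every ordered module pair and threshold at mean + 1 SD.

    The SD is the population (n-denominator) standard deviation by
    default; inclusion is strict (score > threshold).  Also reports each
    module's out-degree and the fraction of other modules it regulates.
    """
    mods = modules.modules
    if len(mods) < 2:
        raise ValueError("need at least 2 modules")
    rows = []
    for u in mods:
        for v in mods:
            if u == v:
                continue
            rows.append(dict(**{"from": u, "to": v},
                             score=module_regulation_score(modules, annot, u, v)))
    df = pd.DataFrame(rows)
    scores = df["score"].values
    thr = float(scores.mean() + scores.std(ddof=0 if population_sd else 1))
    df["is_edge"] = df["score"] > thr
    warns = []
    if np.allclose(scores, scores[0]):
        warns.append("all regulation scores identical; zero edges")
        df["is_edge"] = False
    frac = df.groupby("from")["is_edge"].mean().rename("fraction_regulated")
    graph = ModuleRegulationGraph(scores=df, threshold=thr, warnings=warns)
    graph.fraction_regulated = frac
    return graph


def regulator_target_correlations(
    expr: pd.DataFrame, annot: pd.DataFrame, regulators_in: set | None = None
):
    """Spearman correlation across samples for every annotated pair.

    Returns ``(pair_table, fraction_negative)``; pairs with a constant
    gene are skipped with a note in the table's attrs.
    """
    notes = []
    rows = []
    sub = annot if regulators_in is None else annot[annot["regulator"].isin(regulators_in)]
    for _, row in sub.iterrows():
        r, t = row["regulator"], row["target"]
        if r not in expr.index or t not in expr.index:
            continue
        x, y = expr.loc[r].values, expr.loc[t].values
        if np.std(x) == 0 or np.std(y) == 0:
            notes.append(f"skipped constant gene pair ({r}, {t})")
            continue
        rho = 1.0 if r == t else float(stats.spearmanr(x, y).statistic)
        rows.append(dict(regulator=r, target=t, rho=rho))
    table = pd.DataFrame(rows, columns=["regulator", "target", "rho"])
    table.attrs["notes"] = notes
    frac_neg = float((table["rho"] < 0).mean()) if len(table) else np.nan
    return table, frac_neg


def regulated_riskgene_table(
    graph: ModuleRegulationGraph,
    modules: ModuleSet,
    annot: pd.DataFrame,
    risk_sets: GeneSetCollection,
) -> pd.DataFrame:
    """Risk genes in downstream modules regulated from an upstream module.

    One row per (gene, downstream module, risk set); a gene targeted by
    several upstream regulators appears once with all of them listed.
    """
    if len(annot) == 0:
        return pd.DataFrame(columns=["gene", "module", "risk_set", "regulators", "upstream_module"])
    rows = []
    for _, e in graph.edges().iterrows():
        u, v = int(e["from"]), int(e["to"])
        genes_u = set(modules.module_genes(u))
        regs = set(annot["regulator"]) & genes_u
        if not regs:
            continue
        tgt_map = annot[annot["regulator"].isin(regs)].groupby("target")["regulator"].agg(
            lambda s: sorted(set(s))
        )
        for g in modules.module_genes(v):
            if g not in tgt_map.index:
                continue
            for name, rset in risk_sets.sets.items():
                if g in rset:
                    rows.append(
                        dict(gene=g, module=v, risk_set=name,
                             regulators=";".join(tgt_map[g]), upstream_module=u)
                    )
    return pd.DataFrame(rows, columns=["gene", "module", "risk_set", "regulators", "upstream_module"])
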