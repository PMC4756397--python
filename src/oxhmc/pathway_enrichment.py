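"""Gene-set testing by logistic regression with probe-count adjustment.

Pathway membership across the gene universe is regressed on test-list
membership plus the number of array probes annotated to each gene, so that
genes hit merely because they carry many probes do not inflate enrichment.
Significant pathways are then grouped: the best pathway absorbs any other
significant pathway whose signal disappears once the best pathway's
membership is added as a covariate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .core_io import EmptyInputError, ValidationError

ALPHA = 0.05
SIZE_BOUNDS = (10, 2000)  # inclusive


@dataclass
class GeneUniverse:
    """Genes with >= 1 probe and >= 1 pathway, plus size-filtered pathways."""

    genes: pd.DataFrame                 # index gene_id: n_probes, in_test_list
    pathways: dict[str, frozenset]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def membership(self, pathway_id: str) -> np.ndarray:
        members = self.pathways[pathway_id]
        return self.gene_ids.isin(members).astype(float)


@dataclass
class PathwayResult:
    pathway_id: str
    coefficient: float
    p_value: float
    significant: bool
    group_leader: str | None = None
    explained_by: str | None = None
    flag: str | None = None


def read_gmt(path) -> dict[str, frozenset]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            fh.write("\t".join([name, "na"] + sorted(gene_sets[name])) + "\n")


def _transitive_parents(edges: list[tuple[str, str]]) -> dict[str, set[str]]:
    """Child -> all ancestors; raises on cycles."""
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
    closure: dict[str, set[str]] = {}

    def visit(node: str, stack: tuple) -> set[str]:
        if node in stack:
            raise ValidationError(f"cycle in ontology parent graph at {node!r}")
        if node in closure:
            return closure[node]
        anc = set()
        for p in parents.get(node, ()):
            anc.add(p)
            anc |= visit(p, stack + (node,))
        closure[node] = anc
        return anc

    for node in list(parents):
        visit(node, ())
    return closure


def build_universe(
    ann: pd.DataFrame,
    gene_sets: dict[str, frozenset],
    test_probes=None,
    ontology_parents: list[tuple[str, str]] | None = None,
    size_bounds: tuple[int, int] = SIZE_BOUNDS,
) -> GeneUniverse:
    """Tally probes per gene, propagate pathway membership to parent terms,
    and size-filter pathways (inclusive bounds)."""
    if not gene_sets:
        raise EmptyInputError("no gene sets supplied")

    counts: dict[str, int] = {}
    for genes in ann["genes"]:
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        raise EmptyInputError("no genes annotated to any probe")

    sets = {pid: set(members) for pid, members in gene_sets.items()}
    if ontology_parents:
        closure = _transitive_parents(ontology_parents)
        for child, ancestors in closure.items():
            if child not in sets:
                continue
            for anc in ancestors:
                sets.setdefault(anc, set()).update(sets[child])

    in_any_pathway = set().union(*sets.values())
    gene_ids = sorted(set(counts) & in_any_pathway)
    if not gene_ids:
        raise EmptyInputError("no gene has both probes and pathway annotation")

    test_genes: set[str] = set()
    if test_probes is not None:
        sub = ann.loc[ann.index.intersection(pd.Index(test_probes))]
        for genes in sub["genes"]:
            test_genes |= set(genes)

    frame = pd.DataFrame(
        {
            "n_probes": [counts[g] for g in gene_ids],
            "in_test_list": [g in test_genes for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    lo, hi = size_bounds
    universe_genes = set(gene_ids)
    kept = {}
    for pid, members in sets.items():
        inside = frozenset(members & universe_genes)
        if lo <= len(inside) <= hi:
            kept[pid] = inside
    return GeneUniverse(genes=frame, pathways=kept)


def _firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Jeffreys-penalized logistic fit; returns (beta, cov)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.pinv((X.T * w) @ X)
    return beta, cov


def _wald_logit(y: np.ndarray, X: np.ndarray, term: int) -> tuple[float, float, str | None]:
    """MLE logistic Wald test for column ``term``; Firth fallback on
    separation or non-convergence."""
    from scipy import stats as sps

    flag = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or not np.all(np.isfinite(res.bse)):
            raise PerfectSeparationError("non-finite standard errors")
        if np.abs(res.params).max() > 20:
            raise PerfectSeparationError("runaway coefficients")
        return float(res.params[term]), float(res.pvalues[term]), None
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        flag = "separation_firth"
    beta, cov = _firth_logit(y, X)
    se = np.sqrt(max(cov[term, term], np.finfo(float).tiny))
    z = beta[term] / se
    p = float(2 * sps.norm.sf(abs(z)))
    return float(beta[term]), p, flag


def _design(universe: GeneUniverse, adjust: bool, extra: np.ndarray | None = None) -> np.ndarray:
    cols = [np.ones(len(universe.genes)), universe.genes["in_test_list"].to_numpy(dtype=float)]
    if adjust:
        cols.append(universe.genes["n_probes"].to_numpy(dtype=float))
    if extra is not None:
        cols.append(extra)
    return np.column_stack(cols)


def test_pathway(
    universe: GeneUniverse,
    pathway_id: str,
    adjust: bool = True,
    alpha: float = ALPHA,
) -> PathwayResult:
    """Does test-list membership predict pathway membership, controlling for
    probes per gene? Enrichment requires a positive coefficient."""
    if pathway_id not in universe.pathways:
        raise ValidationError(f"unknown pathway {pathway_id!r}")
    y = universe.membership(pathway_id)
    X = _design(universe, adjust)
    coef, p, flag = _wald_logit(y, X, term=1)
    return PathwayResult(
        pathway_id=pathway_id,
        coefficient=coef,
        p_value=p,
        significant=bool(p < alpha and coef > 0),
        flag=flag,
    )


def test_all_pathways(universe: GeneUniverse, adjust: bool = True, alpha: float = ALPHA) -> list[PathwayResult]:
    results = [test_pathway(universe, pid, adjust=adjust, alpha=alpha) for pid in sorted(universe.pathways)]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def group_redundant(
    results: list[PathwayResult],
    universe: GeneUniverse,
    alpha: float = ALPHA,
) -> list[PathwayResult]:
    """Iterative redundancy grouping of significant pathways.

    Repeatedly take the most significant ungrouped pathway as leader, refit
    every remaining significant pathway with the leader's membership as an
    extra covariate, and mark pathways whose test term drops below
    significance as explained by the leader.
    """
    ordered = sorted(results, key=lambda r: (r.p_value, r.pathway_id))
    significant = [r for r in ordered if r.significant]
    pending = list(significant)
    while pending:
        leader = pending.pop(0)
        leader.group_leader = leader.pathway_id
        extra = universe.membership(leader.pathway_id)
        still = []
        for r in pending:
            y = universe.membership(r.pathway_id)
            X = _design(universe, adjust=True, extra=extra)
            try:
                coef, p, flag = _wald_logit(y, X, term=1)
            except Exception:
                r.flag = (r.flag or "") + "+refit_failed"
                still.append(r)
                continue
            if p >= alpha or coef <= 0:
                r.explained_by = leader.pathway_id
                r.group_leader = leader.pathway_id
            else:
                still.append(r)
        pending = still
    return ordered


def results_to_frame(results: list[PathwayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "coefficient": r.coefficient,
                "p_value": r.p_value,
                "significant": r.significant,
                "group_leader": r.group_leader,
                "explained_by": r.explained_by,
                "flag": r.flag,
            }
            for r in results
        ]
    )
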