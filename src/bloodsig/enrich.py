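"""Gene-set over-representation statistics against a user-supplied background.

Mirrors the usual functional-annotation workflow: map selected probes to
gene symbols (dropping unannotated probes and duplicate symbols), then test
each gene set for over-representation with the one-sided hypergeometric
(Fisher) tail or its conservative EASE variant (overlap reduced by one),
report fold enrichment, and adjust across terms with Benjamini-Hochberg,
expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BloodsigError


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list  # ordered, deduplicated


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    count: int
    pct: float  # count / query size * 100
    p: float  # one-sided over-representation p
    fold: float
    fdr_pct: float  # Benjamini-Hochberg adjusted p * 100
    genes: list


def read_gmt(path) -> dict[str, GeneSet]:
    """Read a GMT file (name, description, tab-separated members)."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BloodsigError(
                    f"malformed GMT line {ln}: fewer than 3 fields"
                )
            name, desc = fields[0], fields[1]
            seen = set()
            genes = []
            for g in fields[2:]:
                if g and g not in seen:
                    seen.add(g)
                    genes.append(g)
            sets[name] = GeneSet(name=name, description=desc, genes=genes)
    return sets


def write_gmt(sets: Mapping[str, GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets.values():
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def map_probes_to_genes(
    probe_ids: Sequence[str],
    annotation: Mapping[str, str] | pd.DataFrame,
) -> tuple[list, int]:
    """Map probes to gene symbols, dropping unannotated and duplicates.

    ``annotation`` maps probe_id -> gene symbol (a dict, or a DataFrame with
    columns probe_id, gene_symbol).  Returns the ordered unique symbols and
    the number of unannotated probes dropped.
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = dict(
            zip(annotation["probe_id"], annotation["gene_symbol"])
        )
    genes: list = []
    seen: set = set()
    n_unannotated = 0
    for pid in probe_ids:
        sym = annotation.get(pid)
        if sym is None or (isinstance(sym, float) and np.isnan(sym)) or sym == "":
            n_unannotated += 1
            continue
        if sym not in seen:
            seen.add(sym)
            genes.append(sym)
    return genes, n_unannotated


def _tail_p(count: int, term_bg: int, query: int, background: int) -> float:
    """Upper hypergeometric tail P(X >= count)."""
    if count <= 0:
        return 1.0
    return float(stats.hypergeom.sf(count - 1, background, term_bg, query))


def enrich(
    query_genes: Iterable[str],
    background_genes: Iterable[str],
    sets: Mapping[str, GeneSet],
    method: str = "ease",
) -> list[EnrichmentRow]:
    """Per-term over-representation statistics for a query gene list.

    The query must be a subset of the background; each term is intersected
    with the background before testing.  ``method='fisher'`` uses the exact
    hypergeometric upper tail of the 2x2 table; ``method='ease'`` reduces
    the query-term overlap by one (floor 0) before taking the tail, the
    conservative default of annotation-clustering tools.  Fold enrichment is
    (count/|query|) / (|term in background|/|background|), and the
    Benjamini-Hochberg FDR across the reported terms is given in percent.
    """
    if method not in ("fisher", "ease"):
        raise BloodsigError("method must be 'fisher' or 'ease'")
    query = list(dict.fromkeys(query_genes))
    background = set(background_genes)
    offenders = [g for g in query if g not in background]
    if offenders:
        raise BloodsigError(
            f"query genes absent from background: {offenders[:10]}"
        )
    qset = set(query)
    N, nq = len(background), len(query)

    rows = []
    for gs in sets.values():
        term_bg = [g for g in gs.genes if g in background]
        hits = [g for g in term_bg if g in qset]
        count = len(hits)
        eff = count - 1 if method == "ease" else count
        p = _tail_p(eff, len(term_bg), nq, N)
        fold = (
            (count / nq) / (len(term_bg) / N)
            if nq > 0 and len(term_bg) > 0
            else 0.0
        )
        rows.append(
            EnrichmentRow(
                term_id=gs.name,
                term_name=gs.description,
                count=count,
                pct=100.0 * count / nq if nq else 0.0,
                p=p,
                fold=fold,
                fdr_pct=np.nan,
                genes=hits,
            )
        )
    if rows:
        pvals = np.array([r.p for r in rows])
        adj = multipletests(pvals, method="fdr_bh")[1]
        for r, a in zip(rows, adj):
            r.fdr_pct = 100.0 * float(a)
    rows.sort(key=lambda r: r.p)
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "term_name": [r.term_name for r in rows],
            "count": [r.count for r in rows],
            "pct": [r.pct for r in rows],
            "p": [r.p for r in rows],
            "fold_enrichment": [r.fold for r in rows],
            "fdr_pct": [r.fdr_pct for r in rows],
            "genes": [",".join(r.genes) for r in rows],
        }
    )
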