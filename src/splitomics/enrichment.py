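"""Hypergeometric gene-set over-representation and the up/down dichotomy summary.

Enrichment is tested separately for the up- and down-regulated gene
lists against an explicit background universe; the Venn-style
``term_dichotomy`` summary counts how many enriched terms are exclusive
to each direction (a fully dichotomised response has zero overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .stats import adjust_pvalues, fold_enrichment, hypergeometric_tail

__all__ = ["GeneSetCollection", "enrich", "term_dichotomy"]


@dataclass
class GeneSetCollection:
    """Mapping of term id -> member gene ids, with optional display names."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset] = {}
        for term, members in self.sets.items():
            members = frozenset(str(g) for g in members)
            if not members:
                raise ValueError(f"term {term!r} has no members")
            clean[str(term)] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.sets[term]

    def name(self, term: str) -> str:
        return self.names.get(term, term)


def enrich(
    query: set[str],
    sets: GeneSetCollection,
    background: set[str],
    min_overlap: int = 2,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Terms are trimmed to the background before testing (K counts only
    background members).  Records with overlap below ``min_overlap`` are
    not emitted.  BH adjustment is applied over the emitted family and
    rows are sorted by raw p.

    Parameters
    ----------
    on_missing : {"error", "drop"}
        What to do with query genes absent from the background.
    """
    query = set(query)
    background = set(background)
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    stray = query - background
    if stray:
        if on_missing == "drop":
            query = query & background
        else:
            raise ValueError(
                f"{len(stray)} query genes absent from background "
                f"(e.g. {sorted(stray)[:5]}); pass on_missing='drop' to ignore"
            )
    N, n = len(background), len(query)
    rows = []
    for term in sets:
        members = sets[term] & background
        k = len(members & query)
        K = len(members)
        if K == 0 or k < min_overlap:
            continue
        rows.append(
            {
                "term": term,
                "name": sets.name(term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fold_enrichment(k, K, n, N),
                "p": hypergeometric_tail(k, K, n, N),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "name", "k", "n", "K", "N", "fold_enrichment", "p"]
    )
    if len(out):
        out["p_bh"] = adjust_pvalues(out["p"].to_numpy(), "benjamini_hochberg").adjusted
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["p_bh"] = pd.Series(dtype=float)
    return out


def term_dichotomy(
    up_records: pd.DataFrame,
    down_records: pd.DataFrame,
    threshold: float = 0.05,
    column: str = "p_bh",
) -> tuple[int, int, int]:
    """Venn counts of enriched terms: (up only, down only, overlap)."""

    def passing(df: pd.DataFrame) -> set[str]:
        if df is None or not len(df):
            return set()
        return set(df.loc[df[column] < threshold, "term"])

    up, down = passing(up_records), passing(down_records)
    return len(up - down), len(down - up), len(up & down)
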