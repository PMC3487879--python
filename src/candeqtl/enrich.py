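"""Gene-set over-representation testing.

Given a query gene list (e.g. transcripts significantly associated with a
SNP) and a background universe (all genes surviving QC), each gene set is
tested for over-representation with the one-sided Fisher exact test — the
hypergeometric upper tail Pr[X >= count] on the 2x2 membership table — or
its conservative EASE variant, which removes one gene from the overlap
cell before taking the tail. P-values across sets are corrected with the
Benjamini-Hochberg step-up FDR.

Gene sets load from GMT files (tab-separated: set ID, description,
member symbols). Sets are intersected with the universe before testing, so
the reported ``size`` is the in-universe size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .qcnorm import ValidationError

logger = logging.getLogger(__name__)

METHOD_FISHER = "fisher"
METHOD_EASE = "ease"


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; duplicate members collapsed."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        empty = [k for k, (_, members) in self.sets.items() if not members]
        if empty:
            raise ValidationError(f"empty gene sets not allowed: {empty[:5]}")

    @classmethod
    def from_gmt(cls, path: str) -> "GeneSetCollection":
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValidationError(
                        f"{path}:{lineno}: GMT line needs set_id, description, >=1 member"
                    )
                set_id, description = parts[0], parts[1]
                if set_id in sets:
                    raise ValidationError(f"{path}:{lineno}: duplicate set ID {set_id!r}")
                members = frozenset(m for m in parts[2:] if m)
                sets[set_id] = (description, members)
        logger.info("loaded %d gene sets from %s", len(sets), path)
        return cls(sets=sets, source=path)


@dataclass
class EnrichmentResult:
    set_id: str
    description: str
    count: int      # query hits in the set
    size: int       # set size within the universe
    p_value: float
    fdr: float
    method: str


def _tail_p(count: int, universe_size: int, set_size: int, query_size: int,
            method: str) -> float:
    """Upper hypergeometric tail; EASE subtracts one from the overlap."""
    k = count - 1 if method == METHOD_EASE else count
    if k <= 0:
        return 1.0
    # sf(k-1) = Pr[X >= k] for X ~ Hypergeom(M=universe, n=set, N=query)
    return float(hypergeom.sf(k - 1, universe_size, set_size, query_size))


def bh_fdr(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, *_ = multipletests(p, method="fdr_bh")
    return q


def enrichment_test(
    query: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    method: str = METHOD_FISHER,
) -> list[EnrichmentResult]:
    """Test every gene set for over-representation of the query list.

    Results are sorted by P-value ascending; sets with no member in the
    universe are skipped.

    Raises
    ------
    ValidationError
        If the query is empty or not a subset of the universe.
    """
    if method not in (METHOD_FISHER, METHOD_EASE):
        raise ValidationError(f"method must be fisher or ease, got {method!r}")
    if not query:
        raise ValidationError("query gene list is empty")
    stray = sorted(query - universe)
    if stray:
        raise ValidationError(f"query genes not in universe: {stray[:10]}")

    m = len(universe)
    n_query = len(query)
    rows: list[EnrichmentResult] = []
    for set_id, (description, members) in sets.sets.items():
        in_universe = members & universe
        if not in_universe:
            continue
        count = len(in_universe & query)
        p = _tail_p(count, m, len(in_universe), n_query, method)
        rows.append(EnrichmentResult(
            set_id=set_id, description=description, count=count,
            size=len(in_universe), p_value=p, fdr=np.nan, method=method,
        ))
    if not rows:
        return rows
    q = bh_fdr([r.p_value for r in rows])
    for r, qi in zip(rows, q):
        r.fdr = float(qi)
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    logger.info("enrichment (%s): %d sets tested against universe of %d genes",
                method, len(rows), m)
    return rows
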