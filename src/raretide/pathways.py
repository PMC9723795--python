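"""KEGG-ortholog pathway coverage summaries.

A cluster's metabolic capability is summarized by which pathways have at
least a minimum fraction (default 25 %, inclusive) of their KEGG orthologs
present in the cluster's KO set.  KO -> pathway maps may be many-to-many.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PathwayCoverage:
    pathway_id: str
    n_kos_in_pathway: int
    n_kos_present: int
    coverage: float
    reported: bool


def read_ko_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column tab-separated ko_id -> pathway_id map (many-to-many)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("KO map needs two columns: ko_id, pathway_id")
    mapping: dict[str, set[str]] = {}
    for ko, pw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(ko, set()).add(pw)
    return mapping


def pathway_coverage(
    ko_set: Iterable[str],
    ko_to_pathway: Mapping[str, Iterable[str]],
    min_fraction: float = 0.25,
) -> list[PathwayCoverage]:
    """Coverage of every mapped pathway by the given KO set.

    coverage = |ko_set ∩ pathway KOs| / |pathway KOs|; a pathway is reported
    when coverage >= min_fraction ("at least", inclusive).  KOs absent from
    the map are ignored with a logged count.  Results sorted by pathway id.
    """
    if not ko_to_pathway:
        raise ValueError("ko_to_pathway map is empty")
    ko_set = set(ko_set)
    pathways: dict[str, set[str]] = {}
    for ko, pws in ko_to_pathway.items():
        for pw in pws if not isinstance(pws, str) else [pws]:
            pathways.setdefault(pw, set()).add(ko)

    unknown = {k for k in ko_set if k not in ko_to_pathway}
    if unknown:
        logger.info("%d KOs absent from the pathway map were ignored", len(unknown))

    out = []
    for pw in sorted(pathways):
        members = pathways[pw]
        present = len(ko_set & members)
        coverage = present / len(members)
        out.append(
            PathwayCoverage(
                pathway_id=pw,
                n_kos_in_pathway=len(members),
                n_kos_present=present,
                coverage=coverage,
                reported=coverage >= min_fraction,
            )
        )
    return out


def write_coverage(results: list[PathwayCoverage], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in results]).to_csv(path, sep="\t", index=False)
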