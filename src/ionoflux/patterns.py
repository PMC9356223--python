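"""Element-annotated gene-set pattern analysis.

Differentially expressed genes are mapped onto the mineral elements they
are associated with, through a merged annotation built from two sources:
genes with published mutant evidence of altering the ionome (KIG, Known
Ionomic Genes, carried over by orthology) and genes tagged "ion transport"
in the Gene Ontology with an unambiguous element assignment. Per element,
the up/down direction counts of its annotated DEGs across the four
water-deficit contrasts are summarized into an overall pattern —
up, down, mixed, or none — and DEG memberships across contrasts are
summarized as UpSet-style exclusive intersections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import chain
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ionome import ELEMENTS

logger = logging.getLogger(__name__)

SOURCE_PRECEDENCE = ("KIG", "GO")  # KIG wins on (gene, element) collisions


def _validate_elements(table: pd.DataFrame, vocabulary: Sequence[str]) -> None:
    bad = set(table["element"].dropna()) - set(vocabulary)
    if bad:
        raise ValueError(f"unknown element symbols: {sorted(bad)}")


def merge_gene_lists(
    go_table: pd.DataFrame,
    kig_table: pd.DataFrame,
    vocabulary: Sequence[str] = ELEMENTS,
) -> pd.DataFrame:
    """Merge GO ion-transport and KIG gene-element tables.

    Both inputs need ``gene`` and ``element`` columns; rows whose element is
    missing (GO genes without an unambiguous element assignment) are dropped
    with a logged count. The union is deduplicated on (gene, element) with
    source precedence KIG > GO. Returns columns gene, element, source.
    """
    frames = []
    for tab, source in ((kig_table, "KIG"), (go_table, "GO")):
        if not {"gene", "element"}.issubset(tab.columns):
            raise ValueError(f"{source} table needs 'gene' and 'element' columns")
        t = tab[["gene", "element"]].copy()
        n_drop = int(t["element"].isna().sum())
        if n_drop:
            logger.info("dropping %d %s rows without an element assignment",
                        n_drop, source)
        t = t.dropna(subset=["element"])
        _validate_elements(t, vocabulary)
        t["source"] = source
        frames.append(t)
    merged = pd.concat(frames, ignore_index=True)
    # KIG first, keep='first' enforces precedence on duplicates
    merged["_rank"] = merged["source"].map({s: i for i, s in enumerate(SOURCE_PRECEDENCE)})
    merged = merged.sort_values(["gene", "element", "_rank"], kind="stable")
    merged = merged.drop_duplicates(subset=["gene", "element"], keep="first")
    return merged.drop(columns="_rank").reset_index(drop=True)


def element_direction_counts(
    deg_tables: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Up/down DEG counts per element and contrast.

    ``deg_tables`` maps contrast name to a DEG result table (index gene,
    columns including ``deg`` and ``direction``). A gene annotated with
    several elements counts once for each. A gene flagged DEG with
    log2FC = 0 ('none' direction) is rejected as inconsistent input.
    Returns columns element, contrast, up, down.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    rows = []
    elements = pd.unique(annotation["element"])
    for contrast, tab in deg_tables.items():
        flagged = tab[tab["deg"]] if "deg" in tab.columns else tab
        if "direction" in flagged.columns and (flagged["direction"] == "none").any():
            bad = flagged.index[flagged["direction"] == "none"].tolist()
            raise ValueError(
                f"DEG flag with zero log2FC is inconsistent: {bad[:5]}"
            )
        ann = annotation[annotation["gene"].isin(flagged.index)]
        for el in elements:
            genes = ann.loc[ann["element"] == el, "gene"]
            dirs = flagged.loc[flagged.index.intersection(genes), "direction"]
            rows.append(
                (el, contrast, int((dirs == "up").sum()), int((dirs == "down").sum()))
            )
    return pd.DataFrame(rows, columns=["element", "contrast", "up", "down"])


def classify_pattern(up: int, down: int, dominance: float = 0.75) -> str:
    """Overall expression pattern of an element's annotated DEGs.

    'none' when no DEG; 'up' ('down') when the up (down) fraction reaches
    the dominance threshold; 'mixed' otherwise. The threshold
    operationalizes "mostly up/downregulated".
    """
    if up < 0 or down < 0:
        raise ValueError("counts must be non-negative")
    if not 0.5 < dominance <= 1.0:
        raise ValueError("dominance must lie in (0.5, 1]")
    total = up + down
    if total == 0:
        return "none"
    if up / total >= dominance:
        return "up"
    if down / total >= dominance:
        return "down"
    return "mixed"


@dataclass
class ElementPattern:
    """Per-element DEG direction counts and overall pattern."""

    element: str
    up: int
    down: int
    pattern: str


def element_patterns(
    direction_counts: pd.DataFrame, dominance: float = 0.75
) -> pd.DataFrame:
    """Summed direction counts per element and their up/down/mixed/none class."""
    summed = direction_counts.groupby("element")[["up", "down"]].sum()
    summed["pattern"] = [
        classify_pattern(int(u), int(d), dominance)
        for u, d in zip(summed["up"], summed["down"])
    ]
    return summed.reset_index()


def upset_exclusive_intersections(
    named_sets: Mapping[str, set],
    include_empty: bool = False,
) -> pd.DataFrame:
    """Exclusive (UpSet-style) intersection counts of named sets.

    For every non-empty subset of set names, counts the items whose
    membership is exactly that subset. Zero-count subsets are omitted
    unless ``include_empty``; the exclusive counts always sum to the size
    of the union. Output columns: ``sets`` (tuple of member names, in input
    order), ``degree``, ``count``; rows sorted by descending count (UpSet
    convention), ties by degree then name.
    """
    names = list(named_sets)
    if len(names) != len(set(names)):
        raise ValueError("duplicate set names")
    if len(names) > 16:
        raise ValueError("at most 16 sets supported")
    membership: dict = {}
    for i, name in enumerate(names):
        for item in named_sets[name]:
            membership[item] = membership.get(item, 0) | (1 << i)
    tallies: dict[int, int] = {}
    for code in membership.values():
        tallies[code] = tallies.get(code, 0) + 1
    rows = []
    if include_empty:
        for code in range(1, 1 << len(names)):
            tallies.setdefault(code, 0)
    for code, count in tallies.items():
        members = tuple(names[i] for i in range(len(names)) if code & (1 << i))
        rows.append((members, len(members), count))
    out = pd.DataFrame(rows, columns=["sets", "degree", "count"])
    return out.sort_values(
        ["count", "degree", "sets"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)


def log2fc_matrix(
    deg_tables: Mapping[str, pd.DataFrame],
    annotation: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Heatmap-ready gene x contrast log2FC matrix with significance stars.

    Restricted to annotated genes when an annotation is given. Each contrast
    contributes a log2FC column and a star column ('*' where the gene is a
    DEG in that contrast).
    """
    genes: set = set(chain.from_iterable(t.index for t in deg_tables.values()))
    if annotation is not None:
        genes &= set(annotation["gene"])
    idx = pd.Index(sorted(genes), name="gene")
    out = pd.DataFrame(index=idx)
    for contrast, tab in deg_tables.items():
        out[f"log2FC_{contrast}"] = tab["log2FC"].reindex(idx)
        out[f"sig_{contrast}"] = np.where(
            tab["deg"].reindex(idx, fill_value=False), "*", ""
        )
    return out
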