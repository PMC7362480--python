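"""Target evolutionary annotations and the related-chemical-pair rule.

Binding targets are annotated at several evolutionary levels (by default
motif, domain, family and superfamily).  Two targets are *evolutionarily
related* at a level when they are the same target or share at least one
annotation label at that level; two compounds form an evolutionarily related
chemical pair (ERCP) at a level when their binding targets are related at
that level.  Relatedness is binary — sharing more labels does not weight it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

DEFAULT_LEVELS: tuple[str, ...] = ("motif", "domain", "family", "superfamily")


class SchemaError(ValueError):
    """An annotation table violates the expected schema."""


@dataclass
class TargetAnnotation:
    target_id: str
    labels: dict[str, frozenset[str]] = field(default_factory=dict)

    def at(self, level: str) -> frozenset[str]:
        return self.labels.get(level, frozenset())


@dataclass
class AnnotationCatalog:
    annotations: dict[str, TargetAnnotation]
    levels: tuple[str, ...] = DEFAULT_LEVELS

    def __contains__(self, target_id: str) -> bool:
        return target_id in self.annotations

    def targets(self) -> list[str]:
        return list(self.annotations)

    def require(self, target_id: str) -> TargetAnnotation:
        if target_id not in self.annotations:
            raise KeyError(f"unknown target {target_id!r}")
        return self.annotations[target_id]


def catalog_from_records(
    records: Iterable[tuple[str, str, str]],
    levels: tuple[str, ...] = DEFAULT_LEVELS,
) -> AnnotationCatalog:
    """Build a catalog from (target_id, level, label) triples."""
    anns: dict[str, dict[str, set[str]]] = {}
    for target_id, level, label in records:
        if level not in levels:
            raise SchemaError(f"unknown annotation level {level!r}; "
                              f"configured levels are {levels}")
        anns.setdefault(target_id, {}).setdefault(level, set()).add(label)
    return AnnotationCatalog(
        annotations={
            t: TargetAnnotation(t, {lv: frozenset(s) for lv, s in by_level.items()})
            for t, by_level in anns.items()
        },
        levels=levels,
    )


def load_annotations(path: str | Path,
                     levels: tuple[str, ...] = DEFAULT_LEVELS) -> AnnotationCatalog:
    """Load a TSV with columns target_id, level, label (one row per label).

    Duplicate rows collapse under set semantics; a row naming a level outside
    the configured list raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"target_id", "level", "label"}
    if not required <= set(df.columns):
        raise SchemaError(f"annotation table must have columns {sorted(required)}, "
                          f"got {list(df.columns)}")
    return catalog_from_records(
        df[["target_id", "level", "label"]].itertuples(index=False, name=None),
        levels=levels,
    )


def related_targets(catalog: AnnotationCatalog, t: str, level: str) -> set[str]:
    """Targets related to ``t`` at ``level``: ``t`` itself plus every target
    sharing at least one label with it at that level."""
    ann = catalog.require(t)
    mine = ann.at(level)
    out = {t}
    if mine:
        for other_id, other in catalog.annotations.items():
            if other_id != t and mine & other.at(level):
                out.add(other_id)
    return out


def ercp_label(catalog: AnnotationCatalog, target_a: str, target_b: str,
               level: str) -> bool:
    """True iff the two targets are identical or share a label at ``level``."""
    ann_a = catalog.require(target_a)
    ann_b = catalog.require(target_b)
    if target_a == target_b:
        return True
    return bool(ann_a.at(level) & ann_b.at(level))


def targets_related(catalog: AnnotationCatalog,
                    targets_a: Iterable[str], targets_b: Iterable[str],
                    level: str) -> bool:
    """True iff any target in ``targets_a`` is related to any in ``targets_b``."""
    set_b = set(targets_b)
    for ta in targets_a:
        rel = related_targets(catalog, ta, level)
        if rel & set_b:
            return True
    return False


def write_annotations(catalog: AnnotationCatalog, path: str | Path) -> None:
    rows = [
        (t, level, label)
        for t, ann in sorted(catalog.annotations.items())
        for level in catalog.levels
        for label in sorted(ann.at(level))
    ]
    pd.DataFrame(rows, columns=["target_id", "level", "label"]).to_csv(
        path, sep="\t", index=False
    )
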