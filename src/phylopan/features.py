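"""Feature-vs-marker-identity summaries.

Given per-strain sets of categorical features (antibiotic-resistance
elements, biosynthetic gene-cluster families, CAZy families, metabolic
hallmarks) and a marker-identity matrix, compute how many features a pair
of strains shares — and how many are unique to one of the two — as a
function of the marker-identity threshold used to group strains into OTUs.
Also provides the feature-size spectrum and per-feature prevalence
fractions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import itertools

import numpy as np
import pandas as pd

FEATURE_CATEGORIES = ("resistance", "gcf", "cazy", "hallmark")

#: optional per-feature flag vocabularies, mirroring call-confidence /
#: completeness series (used as pre-filters for the overlap curve)
CATEGORY_FLAGS = {
    "resistance": ("strict", "loose"),
    "gcf": ("full", "fragment"),
}


@dataclass
class FeatureAnnotation:
    """Per-strain feature sets of one category."""

    category: str
    sets: dict[str, set[str]]
    flags: dict[str, str] | None = None  # feature id -> flag
    tied_to: dict[str, str] = field(default_factory=dict)  # feature -> gene family

    def __post_init__(self):
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category: {self.category!r}")

    @property
    def strains(self) -> list[str]:
        return list(self.sets)

    def all_features(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out

    def subset_by_flag(self, flag: str) -> "FeatureAnnotation":
        """Restrict to features carrying ``flag`` (e.g. 'strict' calls only)."""
        if self.flags is None:
            raise ValueError(f"annotation '{self.category}' has no flags")
        keep = {f for f, fl in self.flags.items() if fl == flag}
        return FeatureAnnotation(
            category=self.category,
            sets={s: v & keep for s, v in self.sets.items()},
            flags={f: self.flags[f] for f in keep},
            tied_to={f: g for f, g in self.tied_to.items() if f in keep},
        )


def overlap_curve(
    identity: pd.DataFrame,
    features: FeatureAnnotation,
    thresholds: Sequence[float],
    mode: str = "cumulative",
) -> pd.DataFrame:
    """Mean shared and mean unique feature counts versus identity threshold.

    For each threshold t, over all unordered strain pairs whose marker
    identity qualifies (cumulative mode: identity >= t; binned mode:
    t <= identity < next threshold): mean_shared = mean |A∩B| and
    mean_unique = mean |A△B|.  Thresholds must be strictly increasing;
    rows with no qualifying pair report n_pairs=0 and NA means.
    """
    thresholds = list(thresholds)
    if any(not 0 <= t <= 100 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 100]")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if mode not in ("cumulative", "binned"):
        raise ValueError("mode must be 'cumulative' or 'binned'")
    strains = [s for s in features.strains if s in identity.index]
    missing = set(features.strains) - set(identity.index)
    if missing:
        raise ValueError(f"strains missing from identity matrix: {sorted(missing)}")
    pairs = list(itertools.combinations(strains, 2))
    idents = np.array([identity.loc[a, b] for a, b in pairs], dtype=float)
    shared = np.array([len(features.sets[a] & features.sets[b]) for a, b in pairs])
    unique = np.array([len(features.sets[a] ^ features.sets[b]) for a, b in pairs])
    rows = []
    for k, t in enumerate(thresholds):
        if mode == "cumulative":
            mask = idents >= t
        else:
            upper = thresholds[k + 1] if k + 1 < len(thresholds) else np.inf
            mask = (idents >= t) & (idents < upper)
        n = int(mask.sum())
        rows.append((
            t, n,
            float(shared[mask].mean()) if n else np.nan,
            float(unique[mask].mean()) if n else np.nan,
        ))
    return pd.DataFrame(rows, columns=["threshold", "n_pairs", "mean_shared", "mean_unique"])


def feature_spectra(features: FeatureAnnotation) -> tuple[pd.Series, pd.Series]:
    """Family-size histogram and per-feature prevalence fractions.

    The histogram counts, for each carrier count, how many features are
    carried by exactly that many strains.  Prevalence fractions are
    carriers / total strains; features carried by no strain are excluded
    from the fraction report.
    """
    if not features.sets:
        raise ValueError("empty annotation")
    n_strains = len(features.sets)
    counts: dict[str, int] = {}
    for s in features.sets.values():
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    for f in features.all_features():
        counts.setdefault(f, 0)
    sizes = pd.Series(counts, name="n_strains_carrying").sort_index()
    hist = sizes.value_counts().sort_index()
    hist.index.name = "family_size"
    prevalence = (sizes[sizes > 0] / n_strains).rename("prevalence_fraction")
    return hist, prevalence


def write_feature_tsv(features: Iterable[FeatureAnnotation], path) -> None:
    rows = []
    for ann in features:
        for strain, fs in ann.sets.items():
            for f in sorted(fs):
                flag = ann.flags.get(f, "") if ann.flags else ""
                rows.append((strain, ann.category, f, flag))
    pd.DataFrame(rows, columns=["strain", "category", "feature_id", "flag"]).to_csv(
        path, sep="\t", index=False
    )


def read_feature_tsv(path) -> dict[str, FeatureAnnotation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, FeatureAnnotation] = {}
    for cat, sub in df.groupby("category"):
        sets: dict[str, set[str]] = {}
        flags: dict[str, str] = {}
        for _, row in sub.iterrows():
            sets.setdefault(row["strain"], set()).add(row["feature_id"])
            if row.get("flag"):
                flags[row["feature_id"]] = row["flag"]
        out[cat] = FeatureAnnotation(category=cat, sets=sets, flags=flags or None)
    return out
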