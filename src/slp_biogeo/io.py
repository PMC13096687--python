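"""Trait/distribution tables, region catalogs, and tree-table alignment.

Tables are UTF-8, tab-delimited; a genus's region list is pipe-delimited
inside one column.  ``align_dataset`` intersects the genus table with the
tree, applies the biogeographic coding, and returns the order-aligned
dataset every downstream analysis consumes, with a provenance record of
what was dropped and why.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import CodingConfig, classify_region_tropical, code_genus, genus_centroid
from .tree import Phylogeny

__all__ = [
    "GenusRecord",
    "RegionCatalog",
    "AnalysisDataset",
    "read_genus_table",
    "write_genus_table",
    "read_region_catalog",
    "write_region_catalog",
    "align_dataset",
    "subset_by_family",
]

REGION_DELIMITER = "|"


@dataclass(frozen=True)
class GenusRecord:
    """One genus: trait state, family, species richness, occupied regions."""

    genus: str
    family: str
    slp: int
    species_richness: int | None
    regions: frozenset[str]

    def __post_init__(self):
        if self.slp not in (0, 1):
            raise ValueError(f"{self.genus}: slp must be 0 or 1, got {self.slp!r}")
        if self.species_richness is not None and self.species_richness < 1:
            raise ValueError(f"{self.genus}: species_richness must be >= 1")


class RegionCatalog:
    """Botanical-country metadata: latitudinal extent, centroid, hotspot flag."""

    COLUMNS = ["region", "min_lat", "max_lat", "centroid_lon", "centroid_lat", "hotspot"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"region catalog missing columns {missing}")
        t = table[self.COLUMNS].copy()
        if t["region"].duplicated().any():
            raise ValueError("duplicate region identifiers")
        if ((t["min_lat"] > t["max_lat"]) | (t["min_lat"] < -90) | (t["max_lat"] > 90)).any():
            raise ValueError("invalid latitudinal extent")
        if not t["hotspot"].isin([0, 1]).all():
            raise ValueError("hotspot flag must be 0/1")
        self.table = t.set_index("region", drop=False)

    def __len__(self):
        return len(self.table)

    def __contains__(self, region):
        return region in self.table.index

    @property
    def regions(self) -> list[str]:
        return self.table["region"].tolist()

    def tropical_flags(self, config: CodingConfig) -> pd.Series:
        return self.table.apply(
            lambda r: classify_region_tropical((r["min_lat"], r["max_lat"]), config),
            axis=1,
        )

    def hotspot_flags(self) -> pd.Series:
        return self.table["hotspot"].astype(int)

    def centroid(self, region) -> tuple[float, float]:
        row = self.table.loc[region]
        return (float(row["centroid_lon"]), float(row["centroid_lat"]))


@dataclass
class AnalysisDataset:
    """Tree-aligned analysis table.

    ``trait``, the rows of ``design`` (columns tropical, hotspot, richness),
    ``families`` and ``centroids`` are all in the order of
    ``phylogeny.tip_labels``.
    """

    phylogeny: Phylogeny
    trait: np.ndarray
    design: pd.DataFrame
    families: list[str]
    centroids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.phylogeny.n_tips
        if not (len(self.trait) == len(self.design) == len(self.families) == n):
            raise ValueError("dataset components are not aligned to the tree")
        if list(self.design.index) != self.phylogeny.tip_labels:
            raise ValueError("design rows must be indexed by tip labels, in tip order")

    @property
    def n(self) -> int:
        return self.phylogeny.n_tips

    @property
    def genera(self) -> list[str]:
        return self.phylogeny.tip_labels

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, indent=2, sort_keys=True)


def _parse_regions(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    parts = [p.strip() for p in str(cell).split(REGION_DELIMITER)]
    return frozenset(p for p in parts if p)


def read_genus_table(path) -> list[GenusRecord]:
    """Read the tab-delimited genus table.

    Expected columns: genus, family, slp, species_richness, regions
    (pipe-delimited list).  Duplicated genera and slp values outside {0, 1}
    are errors; an empty region list or missing richness is preserved on the
    record and handled at alignment time.
    """
    df = pd.read_csv(path, sep="\t", dtype={"genus": str, "family": str})
    required = ["genus", "family", "slp", "species_richness", "regions"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"genus table missing columns {missing}")
    if df["genus"].duplicated().any():
        dups = df.loc[df["genus"].duplicated(), "genus"].tolist()
        raise ValueError(f"duplicated genera: {dups[:5]}")
    records = []
    for row in df.itertuples(index=False):
        slp = row.slp
        if slp not in (0, 1):
            raise ValueError(f"{row.genus}: slp must be 0 or 1, got {slp!r}")
        rich = row.species_richness
        rich = None if pd.isna(rich) else int(rich)
        records.append(
            GenusRecord(
                genus=str(row.genus),
                family=str(row.family),
                slp=int(slp),
                species_richness=rich,
                regions=_parse_regions(row.regions),
            )
        )
    return records


def write_genus_table(records, path) -> None:
    rows = [
        {
            "genus": r.genus,
            "family": r.family,
            "slp": r.slp,
            "species_richness": r.species_richness,
            "regions": REGION_DELIMITER.join(sorted(r.regions)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_region_catalog(path) -> RegionCatalog:
    return RegionCatalog(pd.read_csv(path, sep="\t", dtype={"region": str}))


def write_region_catalog(catalog: RegionCatalog, path) -> None:
    catalog.table.to_csv(path, sep="\t", index=False)


def align_dataset(
    genera,
    tree: Phylogeny,
    catalog: RegionCatalog,
    config: CodingConfig = CodingConfig(),
    tropic_config: CodingConfig | None = None,
) -> AnalysisDataset:
    """Code genera, intersect with the tree, and build the aligned dataset.

    ``tropic_config`` overrides the threshold for the tropical coding only
    (the hotspot coding always uses ``config``), mirroring the sensitivity
    analysis in which only the tropical threshold is raised.

    Genera are dropped — and counted in provenance — when they are absent
    from the tree, occupy no catalogued region, or lack species richness.
    """
    tconf = tropic_config if tropic_config is not None else config
    trop_flags = catalog.tropical_flags(tconf)
    hot_flags = catalog.hotspot_flags()

    tree_tips = set(tree.tip_labels)
    drops = {"absent_from_tree": 0, "missing_distribution": 0,
             "missing_richness": 0, "unknown_regions_ignored": 0}
    coded = {}
    for rec in genera:
        if rec.genus not in tree_tips:
            drops["absent_from_tree"] += 1
            continue
        known = [r for r in rec.regions if r in catalog]
        drops["unknown_regions_ignored"] += len(rec.regions) - len(known)
        if not known:
            drops["missing_distribution"] += 1
            continue
        if rec.species_richness is None:
            drops["missing_richness"] += 1
            continue
        tropical = code_genus([trop_flags[r] for r in known], tconf)
        hotspot = code_genus([hot_flags[r] for r in known], config)
        centroid = genus_centroid([catalog.centroid(r) for r in known])
        coded[rec.genus] = (rec.family, rec.slp, tropical, hotspot,
                            rec.species_richness, centroid)
    if len(coded) < 2:
        raise ValueError("fewer than 2 genera shared between table and tree")
    pruned = tree.prune_to(sorted(coded))
    order = pruned.tip_labels
    fam, slp, trop, hot, rich, cent = zip(*(coded[g] for g in order))
    design = pd.DataFrame(
        {"tropical": trop, "hotspot": hot, "richness": rich},
        index=pd.Index(order, name="genus"),
        dtype=float,
    )
    prov = dict(drops)
    prov["n_input"] = len(list(genera)) if not hasattr(genera, "__len__") else len(genera)
    prov["n_retained"] = len(order)
    prov["tropic_threshold"] = tconf.occupancy_threshold
    prov["hotspot_threshold"] = config.occupancy_threshold
    return AnalysisDataset(
        phylogeny=pruned,
        trait=np.array(slp, dtype=np.int64),
        design=design,
        families=list(fam),
        centroids=np.array(cent, dtype=float),
        provenance=prov,
    )


def subset_by_family(dataset: AnalysisDataset, family: str, mode: str = "include") -> AnalysisDataset:
    """Restrict a dataset to one family (``include``) or its complement
    (``exclude``); include/exclude subsets partition the parent."""
    if mode not in ("include", "exclude"):
        raise ValueError("mode must be 'include' or 'exclude'")
    fams = np.array(dataset.families)
    if mode == "include":
        if family not in set(dataset.families):
            raise ValueError(f"family {family!r} not present in dataset")
        mask = fams == family
    else:
        mask = fams != family
    labels = [g for g, m in zip(dataset.genera, mask) if m]
    if len(labels) == len(dataset.genera):
        return dataset
    pruned = dataset.phylogeny.prune_to(labels)
    order = pruned.tip_labels
    idx = {g: i for i, g in enumerate(dataset.genera)}
    sel = np.array([idx[g] for g in order])
    prov = dict(dataset.provenance)
    prov["subset"] = {"family": family, "mode": mode, "parent_n": dataset.n}
    return AnalysisDataset(
        phylogeny=pruned,
        trait=dataset.trait[sel],
        design=dataset.design.iloc[sel],
        families=[dataset.families[i] for i in sel],
        centroids=dataset.centroids[sel],
        provenance=prov,
    )
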