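"""Readers, writers and validation for the external artifacts of a paired
DNA/RNA metabarcoding survey.

Every table crossing the package boundary is plain TSV (UTF-8, ``#``-prefixed
comment lines); trees are newick.  The in-memory containers are thin,
validated wrappers around :class:`pandas.DataFrame` and
:class:`skbio.TreeNode` — downstream modules operate on these, never on raw
files.

Conventions
-----------
* Count tables are oriented ASVs-as-rows, samples-as-columns.  A transposed
  file is only auto-detected when the first header cell is the sentinel
  ``#ASV_ID``; anything else is rejected rather than silently transposed.
* Habitats follow the ROV survey design: ROV1–ROV3 are seep sites,
  ROV4–ROV5 non-seep reference sites.
* All result writers emit a ``#``-prefixed header recording the software
  version and any parameters (including seeds) used to produce the table.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CommunityTable",
    "Phylogeny",
    "TaxonomyMap",
    "PairedCommunity",
    "SEEP_HABITATS",
    "NONSEEP_HABITATS",
    "region_of_habitat",
    "read_community_table",
    "write_community_table",
    "read_newick",
    "write_newick",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "pair_samples",
    "write_result_table",
]

logger = logging.getLogger(__name__)

SEEP_HABITATS = ("ROV1", "ROV2", "ROV3")
NONSEEP_HABITATS = ("ROV4", "ROV5")

#: default suffixes stripped from sample ids to recover the shared physical
#: sample key when pairing DNA with RNA libraries
DEFAULT_PAIR_SUFFIXES = ("_DNA", "_RNA", "_cDNA")


class TableFormatError(ValueError):
    """Structural problem in an on-disk table (duplicates, bad orientation)."""


class ValidationError(ValueError):
    """Content violates a domain invariant (negative count, all-zero sample)."""


def region_of_habitat(habitat: str) -> str:
    """Map an ROV habitat label to its region class (``seep``/``non-seep``)."""
    if habitat in SEEP_HABITATS:
        return "seep"
    if habitat in NONSEEP_HABITATS:
        return "non-seep"
    raise ValidationError(f"unknown habitat label {habitat!r}; expected ROV1..ROV5")


@dataclass
class CommunityTable:
    """Integer ASV × sample count matrix.

    Parameters
    ----------
    counts
        DataFrame with ASV identifiers as the index and sample identifiers
        as columns.  All cells must be non-negative integers and every
        sample (column) must contain at least one read.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise TableFormatError("duplicate ASV identifiers in count table")
        if c.columns.has_duplicates:
            raise TableFormatError("duplicate sample identifiers in count table")
        arr = c.to_numpy()
        if arr.size == 0:
            raise ValidationError("empty count table")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric cells in count table")
        if np.any(arr < 0):
            raise ValidationError("negative counts in count table")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("non-integer counts in count table")
        self.counts = c.astype(np.int64)
        zero = self.counts.sum(axis=0) == 0
        if zero.any():
            bad = ", ".join(self.counts.columns[zero])
            raise ValidationError(f"all-zero sample(s): {bad}")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        return CommunityTable(self.counts.loc[:, list(sample_ids)])

    def drop_empty_asvs(self) -> "CommunityTable":
        keep = self.counts.sum(axis=1) > 0
        return CommunityTable(self.counts.loc[keep])


@dataclass
class Phylogeny:
    """Rooted tree over ASV tips with branch lengths.

    Wraps a :class:`skbio.TreeNode`; patristic distances are memoised since
    the matrix is reused heavily by the assembly null model.
    """

    tree: TreeNode
    _patristic: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if len(tips) != len(set(tips)):
            raise TableFormatError("duplicate tip labels in phylogeny")
        n_zero = 0
        n_edges = 0
        for node in self.tree.traverse(include_self=False):
            n_edges += 1
            if node.length is None:
                node.length = 0.0
                n_zero += 1
            elif node.length < 0:
                raise ValidationError("negative branch length in phylogeny")
            elif node.length == 0:
                n_zero += 1
        if n_zero:
            logger.warning("phylogeny: %d/%d zero/missing branch lengths", n_zero, n_edges)
        if n_edges and n_zero / n_edges > 0.01:
            logger.warning(
                "phylogeny: >1%% zero-length branches; nearest-taxon distances degenerate"
            )

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.tips())

    def total_branch_length(self) -> float:
        return sum(
            n.length or 0.0 for n in self.tree.traverse(include_self=False)
        )

    def patristic_matrix(self):
        """Pairwise tip-to-tip path-length distances (skbio DistanceMatrix)."""
        if self._patristic is None:
            self._patristic = self.tree.tip_tip_distances()
        return self._patristic

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()


class TaxonomyMap:
    """ASV → ranked lineage, with a designated "group" rank for roll-ups.

    The group rank is the class level for prokaryotes and typically the
    phylum level for microeukaryotes; it indexes every group-level summary
    (abundant groups, seep-active groups).
    """

    RANKS = ("domain", "phylum", "class", "order", "family", "genus")

    def __init__(self, lineages: Mapping[str, Sequence[str]], group_rank: str = "class"):
        if group_rank not in self.RANKS:
            raise ValueError(f"group_rank must be one of {self.RANKS}")
        self.group_rank = group_rank
        self._rank_idx = self.RANKS.index(group_rank)
        self._lineages: dict[str, tuple[str, ...]] = {}
        for asv, lin in lineages.items():
            lin = tuple(lin)[: len(self.RANKS)]
            lin = lin + ("unclassified",) * (len(self.RANKS) - len(lin))
            self._lineages[asv] = lin

    def __contains__(self, asv: str) -> bool:
        return asv in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def lineage(self, asv: str) -> tuple[str, ...]:
        return self._lineages[asv]

    def group(self, asv: str) -> str:
        """Group-rank label for an ASV; ``unclassified`` when absent."""
        lin = self._lineages.get(asv)
        return lin[self._rank_idx] if lin is not None else "unclassified"

    def groups(self, asv_ids: Iterable[str]) -> pd.Series:
        ids = list(asv_ids)
        return pd.Series([self.group(a) for a in ids], index=ids, name="group")


@dataclass
class PairedCommunity:
    """Matched DNA and RNA count tables sharing physical sample identity.

    ``pairs`` maps each retained physical sample to its
    ``(dna_sample_id, rna_sample_id)`` library columns.  Unpaired samples are
    dropped before any DNA-vs-RNA comparison.
    """

    dna: CommunityTable
    rna: CommunityTable
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        dna_cols = set(self.dna.sample_ids)
        rna_cols = set(self.rna.sample_ids)
        seen_d: set[str] = set()
        seen_r: set[str] = set()
        for d, r in self.pairs:
            if d not in dna_cols:
                raise ValidationError(f"pair references unknown DNA sample {d!r}")
            if r not in rna_cols:
                raise ValidationError(f"pair references unknown RNA sample {r!r}")
            if d in seen_d or r in seen_r:
                raise ValidationError("a sample participates in more than one pair")
            seen_d.add(d)
            seen_r.add(r)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})


def read_community_table(path) -> CommunityTable:
    """Read an ASV × sample count table from TSV.

    The first column holds ASV ids, the header row sample ids.  A file whose
    top-left header cell is the sentinel ``#ASV_ID`` is accepted as-is (the
    sentinel marks the canonical orientation); any other orientation hint is
    the caller's responsibility.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # "#"-prefixed lines are comments, except the canonical "#ASV_ID" header
    # sentinel, which marks the orientation and must survive as the header
    lines = [
        ln for ln in path.read_text().splitlines()
        if not ln.startswith("#") or ln.startswith("#ASV_ID")
    ]
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        num = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in {path.name}: {exc}") from exc
    return CommunityTable(num)


def write_community_table(
    table: CommunityTable, path, params: Mapping[str, object] | None = None
) -> None:
    write_result_table(table.counts, path, params, index_label="#ASV_ID")


def read_newick(path_or_str) -> Phylogeny:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    s = str(path_or_str)
    if "(" in s and ";" in s:
        handle = _io.StringIO(s)
    else:
        p = Path(path_or_str)
        if not p.exists():
            raise FileNotFoundError(p)
        handle = _io.StringIO(p.read_text())
    try:
        tree = TreeNode.read(handle, format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise TableFormatError(f"unparseable newick: {exc}") from exc
    return Phylogeny(tree)


def write_newick(phy: Phylogeny, path) -> None:
    Path(path).write_text(phy.to_newick() + "\n")


def read_taxonomy(path, group_rank: str = "class") -> TaxonomyMap:
    """Read a two-column TSV ``asv_id<TAB>semicolon-delimited lineage``."""
    lineages: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TableFormatError(f"taxonomy line lacks a lineage: {line!r}")
        asv = parts[0].strip()
        if asv in lineages:
            raise TableFormatError(f"duplicate taxonomy entry for {asv!r}")
        lineages[asv] = [r.strip() for r in parts[1].split(";")]
    return TaxonomyMap(lineages, group_rank=group_rank)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#ASV_ID\tlineage\n")
        for asv in sorted(tax._lineages):
            fh.write(f"{asv}\t{';'.join(tax.lineage(asv))}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (mandatory columns: sample_id, habitat,
    depth_cmbs); derives the ``region`` column from habitat and validates
    depth range 0–70 cmbs."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "habitat", "depth_cmbs"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise TableFormatError("duplicate sample_id in metadata")
    depth = pd.to_numeric(df["depth_cmbs"])
    if (depth < 0).any() or (depth > 70).any():
        raise ValidationError("depth_cmbs outside the surveyed 0-70 cmbs range")
    df = df.copy()
    df["depth_cmbs"] = depth
    df["region"] = [region_of_habitat(h) for h in df["habitat"]]
    return df.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path, params=None) -> None:
    write_result_table(meta.reset_index(drop=True), path, params, index=False)


def write_result_table(
    df: pd.DataFrame,
    path,
    params: Mapping[str, object] | None = None,
    index_label: str | None = None,
    index: bool = True,
) -> None:
    """Write a TSV with a ``#`` header recording software version + params."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# seepecol {__version__}\n")
        for k, v in (params or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def strip_library_suffix(sample_id: str, suffixes: Sequence[str] = DEFAULT_PAIR_SUFFIXES) -> str:
    """Recover the physical sample key by stripping a library-type suffix."""
    for suf in suffixes:
        if sample_id.endswith(suf):
            return sample_id[: -len(suf)]
    return sample_id


def pair_samples(
    dna: CommunityTable,
    rna: CommunityTable,
    metadata: pd.DataFrame | None = None,
    max_depth_cmbs: float = 10.0,
    suffixes: Sequence[str] = DEFAULT_PAIR_SUFFIXES,
) -> PairedCommunity:
    """Match DNA samples to their RNA counterparts.

    Samples pair when their ids agree after stripping a library suffix
    (``_DNA``/``_RNA``/``_cDNA`` by default).  Pairs whose sediment depth
    exceeds ``max_depth_cmbs`` are excluded — diversity comparisons are
    restricted to the surface layers where both libraries exist.  Unpaired
    samples are reported at INFO level; zero resulting pairs is an error.
    """
    dna_key = {strip_library_suffix(s, suffixes): s for s in dna.sample_ids}
    rna_key = {strip_library_suffix(s, suffixes): s for s in rna.sample_ids}
    shared = sorted(set(dna_key) & set(rna_key))

    dropped_depth: list[str] = []
    pairs: list[tuple[str, str]] = []
    for key in shared:
        if metadata is not None:
            row = None
            for candidate in (key, dna_key[key], rna_key[key]):
                if candidate in metadata.index:
                    row = metadata.loc[candidate]
                    break
            if row is not None and float(row["depth_cmbs"]) > max_depth_cmbs:
                dropped_depth.append(key)
                continue
        pairs.append((dna_key[key], rna_key[key]))

    unpaired_dna = sorted(set(dna_key) - set(rna_key))
    unpaired_rna = sorted(set(rna_key) - set(dna_key))
    if unpaired_dna:
        logger.info("pair_samples: unpaired DNA samples: %s", unpaired_dna)
    if unpaired_rna:
        logger.info("pair_samples: unpaired RNA samples: %s", unpaired_rna)
    if dropped_depth:
        logger.info(
            "pair_samples: %d pairs beyond %.1f cmbs dropped: %s",
            len(dropped_depth), max_depth_cmbs, dropped_depth,
        )
    if not pairs:
        raise ValidationError("no DNA/RNA sample pairs could be formed")

    dna_sub = dna.subset_samples([d for d, _ in pairs])
    rna_sub = rna.subset_samples([r for _, r in pairs])
    return PairedCommunity(dna_sub, rna_sub, pairs)
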