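"""In-memory containers and plain-text readers/writers for study objects.

Everything the pipeline consumes travels in simple tab-separated or
MatrixMarket formats: a gene x cell expression matrix, a cell annotation
table, gene-set collections (GMT), an ortholog map, a ligand-receptor
interaction table, and a protein-protein interaction edge list.

Gene identity is the plain symbol string, case-sensitive.  Cross-species
comparison goes exclusively through :class:`OrthologMap`; symbols are never
matched by name across species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

AGE_GROUPS = ("young", "old")

ANNOTATION_COLUMNS = ["cell_id", "species", "cell_type", "age_group"]
ORTHOLOG_COLUMNS = ["species_a", "gene_a", "species_b", "gene_b"]
LR_COLUMNS = [
    "interaction",
    "pathway",
    "ligand",
    "receptor",
    "agonist",
    "antagonist",
    "co_stim",
    "co_inhib",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-major expression matrix (genes are rows, cells are columns).

    ``values`` holds raw counts (``normalized=False``) or CP10k+log1p
    normalized expression (``normalized=True``).  All values are >= 0 and
    gene/cell id lists are unique and match the matrix dimensions.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        """Expression of one gene across all cells; zeros if absent."""
        i = self._gene_index.get(gene)
        if i is None:
            return np.zeros(self.n_cells)
        return self.values[i]

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._cell_index[c] for c in cell_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=list(cell_ids),
            values=self.values[:, idx],
            normalized=self.normalized,
        )

    def equals(self, other: "ExpressionMatrix", atol: float = 0.0) -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and self.normalized == other.normalized
            and np.allclose(self.values, other.values, atol=atol, rtol=0.0)
        )


def normalize_log1p_cp10k(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to 10,000 total counts, then apply log(1+x).

    All-zero cells are left all-zero.  Applying the transform twice is an
    error: the flag on the input must be ``False``.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    totals = m.values.sum(axis=0)
    scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
    values = np.log1p(m.values * scale[np.newaxis, :])
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        values=values,
        normalized=True,
    )


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    normalized: bool = False,
) -> ExpressionMatrix:
    """Read a gene x cell matrix from MatrixMarket or dense TSV.

    A ``.mtx`` file requires ``genes_path`` / ``cells_path`` sidecars with one
    id per line.  A dense TSV has cell ids in the header row and gene ids in
    the first column.  Sparse and dense inputs with equal content produce
    equal objects.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise FormatError("MatrixMarket input requires gene and cell id sidecars")
        genes = _read_id_column(genes_path)
        cells = _read_id_column(cells_path)
        values = np.asarray(mmread(str(matrix_path)).todense(), dtype=float)
        if values.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix is {values.shape} but sidecars list "
                f"{len(genes)} genes and {len(cells)} cells"
            )
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise FormatError("negative expression value in input")
    return ExpressionMatrix(genes, cells, values, normalized=normalized)


def write_expression_mtx(
    m: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    mmwrite(str(matrix_path), coo_matrix(m.values))
    Path(genes_path).write_text("".join(f"{g}\n" for g in m.gene_ids))
    Path(cells_path).write_text("".join(f"{c}\n" for c in m.cell_ids))


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
    df.to_csv(path, sep="\t", index_label="gene")


def _read_id_column(path: str | Path) -> list[str]:
    # Sidecars are one id per line; a second tab-separated column (10x-style
    # gene symbol) is tolerated and ignored.
    ids = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            ids.append(line.split("\t")[0].strip())
    if not ids:
        raise FormatError(f"empty id file: {path}")
    return ids


# ---------------------------------------------------------------------------
# Cell annotations
# ---------------------------------------------------------------------------


@dataclass
class CellAnnotation:
    """One row per cell: species, cell type and age group (young/old)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        self.table = self.table[ANNOTATION_COLUMNS].reset_index(drop=True)
        if self.table["cell_id"].duplicated().any():
            dupes = self.table.loc[self.table["cell_id"].duplicated(), "cell_id"]
            raise ValueError(f"duplicate cell ids in annotation: {list(dupes)[:5]}")
        bad = set(self.table["age_group"]) - set(AGE_GROUPS)
        if bad:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}, got {sorted(bad)}")

    def cells(
        self,
        species: str | None = None,
        cell_type: str | None = None,
        age_group: str | None = None,
    ) -> list[str]:
        t = self.table
        if species is not None:
            t = t[t["species"] == species]
        if cell_type is not None:
            t = t[t["cell_type"] == cell_type]
        if age_group is not None:
            t = t[t["age_group"] == age_group]
        return list(t["cell_id"])

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())


def read_annotations(path: str | Path) -> CellAnnotation:
    return CellAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotations(ann: CellAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets; member lists are deduplicated, order preserved."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"empty GMT file: {path}")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Ortholog map
# ---------------------------------------------------------------------------


@dataclass
class OrthologMap:
    """Direction-free gene correspondences between species pairs."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ORTHOLOG_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"ortholog table missing columns: {missing}")
        self.table = self.table[ORTHOLOG_COLUMNS].drop_duplicates().reset_index(drop=True)

    def one_to_one(self, species_a: str, species_b: str) -> dict[str, str]:
        """Mapping gene_a -> gene_b keeping only one-to-one pairs.

        Records are direction-free, so both orientations in the table are
        considered.  Genes with more than one partner are dropped.
        """
        t = self.table
        fwd = t[(t["species_a"] == species_a) & (t["species_b"] == species_b)]
        rev = t[(t["species_a"] == species_b) & (t["species_b"] == species_a)]
        pairs = pd.concat(
            [
                fwd[["gene_a", "gene_b"]],
                rev.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})[
                    ["gene_a", "gene_b"]
                ],
            ]
        ).drop_duplicates()
        counts_a = pairs["gene_a"].value_counts()
        counts_b = pairs["gene_b"].value_counts()
        keep = pairs[
            pairs["gene_a"].map(counts_a).eq(1) & pairs["gene_b"].map(counts_b).eq(1)
        ]
        return dict(zip(keep["gene_a"], keep["gene_b"]))


def read_orthologs(path: str | Path) -> OrthologMap:
    return OrthologMap(pd.read_csv(path, sep="\t", dtype=str))


def write_orthologs(orth: OrthologMap, path: str | Path) -> None:
    orth.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ligand-receptor interaction database
# ---------------------------------------------------------------------------


@dataclass
class LigandReceptor:
    """One interaction: multi-subunit ligand and receptor plus modulators.

    ``agonist``/``antagonist`` are soluble modulator gene lists; ``co_stim``/
    ``co_inhib`` are co-stimulatory / co-inhibitory membrane receptor lists.
    All four may be empty; subunit lists may not.
    """

    name: str
    pathway: str
    ligand: list[str]
    receptor: list[str]
    agonist: list[str] = field(default_factory=list)
    antagonist: list[str] = field(default_factory=list)
    co_stim: list[str] = field(default_factory=list)
    co_inhib: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError(
                f"interaction {self.name!r}: ligand and receptor subunit lists "
                "must be non-empty"
            )


@dataclass
class LigandReceptorDB:
    interactions: list[LigandReceptor]

    def __post_init__(self) -> None:
        names = [x.name for x in self.interactions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate interaction names in ligand-receptor table")

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions)

    @property
    def pathways(self) -> list[str]:
        return sorted({x.pathway for x in self.interactions})


def _split_list(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    s = str(value).strip()
    if not s:
        return []
    return [g.strip() for g in s.split(",") if g.strip()]


def read_lr_database(path: str | Path) -> LigandReceptorDB:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ligand-receptor table missing columns: {missing}")
    interactions = [
        LigandReceptor(
            name=row["interaction"],
            pathway=row["pathway"],
            ligand=_split_list(row["ligand"]),
            receptor=_split_list(row["receptor"]),
            agonist=_split_list(row["agonist"]),
            antagonist=_split_list(row["antagonist"]),
            co_stim=_split_list(row["co_stim"]),
            co_inhib=_split_list(row["co_inhib"]),
        )
        for _, row in df.iterrows()
    ]
    return LigandReceptorDB(interactions)


def write_lr_database(db: LigandReceptorDB, path: str | Path) -> None:
    rows = [
        {
            "interaction": x.name,
            "pathway": x.pathway,
            "ligand": ",".join(x.ligand),
            "receptor": ",".join(x.receptor),
            "agonist": ",".join(x.agonist),
            "antagonist": ",".join(x.antagonist),
            "co_stim": ",".join(x.co_stim),
            "co_inhib": ",".join(x.co_inhib),
        }
        for x in db.interactions
    ]
    pd.DataFrame(rows, columns=LR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Graph edge list
# ---------------------------------------------------------------------------


@dataclass
class GraphEdgeList:
    """Undirected simple graph as (gene_a, gene_b, weight) records.

    Self-loops are removed and duplicate edges (in either orientation)
    collapsed on construction.
    """

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], float] = {}
        for e in self.edges:
            a, b = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else 1.0
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            seen[key] = w
        self.edges = [(a, b, w) for (a, b), w in sorted(seen.items())]

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g


def read_edges(path: str | Path) -> GraphEdgeList:
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: edge line needs two genes")
        if fields[0] == "gene_a" and lineno == 1:  # optional header
            continue
        w = float(fields[2]) if len(fields) > 2 and fields[2].strip() else 1.0
        edges.append((fields[0].strip(), fields[1].strip(), w))
    return GraphEdgeList(edges)


def write_edges(g: GraphEdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in g.edges:
            fh.write(f"{a}\t{b}\t{w:g}\n")
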