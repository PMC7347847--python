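"""Core containers for expression studies and their TSV exchange formats.

An expression study is a log2-scale probe x sample intensity matrix together
with a probe -> gene annotation and per-sample group (histological subtype)
and batch (cohort of origin) labels. Several probes may interrogate the same
gene; probe ids are unique. All on-disk exchange happens through three plain
TSV files (matrix, annotation, metadata) so that any pipeline stage can be
re-run in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: probes whose id starts with this prefix are array controls, dropped at load
CONTROL_PROBE_PREFIX = "AFFX"


class StudyFormatError(ValueError):
    """Malformed input: duplicate ids, non-numeric cells, bad headers."""


class ConsistencyError(ValueError):
    """Cross-file or cross-object mismatch (samples, genes, probe order)."""


@dataclass
class ExpressionStudy:
    """A validated log2 probe x sample expression matrix with annotations.

    Parameters
    ----------
    matrix
        ``(n_probes, n_samples)`` float array of log2 intensities.
    probe_ids
        Unique probe identifiers, one per matrix row.
    gene_symbols
        Gene symbol per probe; many probes may map to one gene.
    sample_ids
        Unique sample identifiers, one per matrix column.
    group
        Histological subtype label per sample (e.g. ``DA``/``AA``/``GBM``).
    batch
        Cohort-of-origin label per sample.
    """

    matrix: np.ndarray
    probe_ids: list[str]
    gene_symbols: list[str]
    sample_ids: list[str]
    group: list[str]
    batch: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.probe_ids = list(map(str, self.probe_ids))
        self.gene_symbols = list(map(str, self.gene_symbols))
        self.sample_ids = list(map(str, self.sample_ids))
        self.group = list(map(str, self.group))
        self.batch = list(map(str, self.batch))
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        j, i = self.matrix.shape
        if len(self.probe_ids) != j:
            raise ConsistencyError(
                f"{len(self.probe_ids)} probe ids for {j} matrix rows"
            )
        if len(self.gene_symbols) != j:
            raise ConsistencyError("gene_symbols length != number of probes")
        if len(self.sample_ids) != i:
            raise ConsistencyError(
                f"{len(self.sample_ids)} sample ids for {i} matrix columns"
            )
        if len(self.group) != i or len(self.batch) != i:
            raise ConsistencyError("group/batch labels must cover every sample")
        if len(set(self.probe_ids)) != j:
            raise StudyFormatError("duplicate probe ids")
        if len(set(self.sample_ids)) != i:
            raise StudyFormatError("duplicate sample ids")
        if np.isnan(self.matrix).any():
            raise StudyFormatError("matrix contains missing values")

    # -- convenience --------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        return list(dict.fromkeys(self.group))

    @property
    def batches(self) -> list[str]:
        return list(dict.fromkeys(self.batch))

    def group_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.group) == label)

    def batch_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.batch) == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.probe_ids, columns=self.sample_ids
        )

    def with_matrix(self, matrix: np.ndarray) -> "ExpressionStudy":
        """Copy of the study with a replaced (same-shape) matrix."""
        if matrix.shape != self.matrix.shape:
            raise ConsistencyError("replacement matrix must keep the shape")
        return replace(self, matrix=np.asarray(matrix, dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionStudy):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and self.gene_symbols == other.gene_symbols
            and self.sample_ids == other.sample_ids
            and self.group == other.group
            and self.batch == other.batch
            and np.array_equal(self.matrix, other.matrix)
        )


@dataclass
class GenePanel:
    """A discriminatory gene panel collapsed from probe-level DE records.

    ``genes`` are unique symbols; ``probes`` lists every contributing probe per
    gene; ``direction`` records in which group each gene is over-expressed.
    """

    genes: list[str]
    probes: dict[str, list[str]] = field(default_factory=dict)
    direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise StudyFormatError("panel genes must be unique")
        seen: dict[str, str] = {}
        for gene, probe_list in self.probes.items():
            for p in probe_list:
                if p in seen and seen[p] != gene:
                    raise ConsistencyError(
                        f"probe {p} assigned to both {seen[p]} and {gene}"
                    )
                seen[p] = gene

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_study(
    matrix_path,
    annotation_path,
    metadata_path,
    *,
    drop_control_probes: bool = True,
    impute_missing: bool = False,
) -> ExpressionStudy:
    """Load a study from the matrix / annotation / metadata TSV trio.

    Probes without a gene symbol in the annotation (and, by default, control
    probes prefixed ``AFFX``) are dropped with a logged count. Missing values
    are rejected unless ``impute_missing`` is set, in which case each gap is
    filled with its probe's mean.
    """
    try:
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise StudyFormatError(f"cannot parse matrix: {exc}") from exc
    if mat.index.has_duplicates:
        raise StudyFormatError("duplicate probe ids in matrix")
    if mat.columns.has_duplicates:
        raise StudyFormatError("duplicate sample ids in matrix")
    values = mat.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & mat.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise StudyFormatError(
            f"non-numeric cell at probe {mat.index[r]!r}, sample {mat.columns[c]!r}"
        )
    if values.isna().to_numpy().any():
        if not impute_missing:
            raise StudyFormatError(
                "matrix contains missing values (set impute_missing to fill "
                "with per-probe means)"
            )
        values = values.T.fillna(values.mean(axis=1)).T

    ann = pd.read_csv(
        annotation_path, sep="\t", index_col=0, dtype=str
    ).iloc[:, 0]
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    if not {"group", "batch"}.issubset(meta.columns):
        raise StudyFormatError("metadata must have 'group' and 'batch' columns")
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ConsistencyError(f"samples missing from metadata: {missing}")

    probe_ids = [str(p) for p in values.index]
    keep, genes = [], []
    n_unannotated = n_control = 0
    for p in probe_ids:
        if drop_control_probes and p.startswith(CONTROL_PROBE_PREFIX):
            n_control += 1
            continue
        g = ann.get(p)
        if g is None or pd.isna(g) or str(g).strip() == "":
            n_unannotated += 1
            continue
        keep.append(p)
        genes.append(str(g))
    if n_unannotated or n_control:
        logger.warning(
            "dropped %d probes without gene symbol and %d control probes",
            n_unannotated,
            n_control,
        )
    values = values.loc[keep]
    samples = [str(s) for s in values.columns]
    meta = meta.loc[samples]
    return ExpressionStudy(
        matrix=values.to_numpy(dtype=float),
        probe_ids=keep,
        gene_symbols=genes,
        sample_ids=samples,
        group=meta["group"].tolist(),
        batch=meta["batch"].tolist(),
    )


def write_study(study: ExpressionStudy, matrix_path, annotation_path, metadata_path) -> None:
    """Write the three-file TSV representation of a study (LF, '.' decimals)."""
    study.to_frame().to_csv(matrix_path, sep="\t", index_label="probe_id")
    pd.DataFrame(
        {"gene_symbol": study.gene_symbols}, index=pd.Index(study.probe_ids, name="probe_id")
    ).to_csv(annotation_path, sep="\t")
    pd.DataFrame(
        {"group": study.group, "batch": study.batch},
        index=pd.Index(study.sample_ids, name="sample_id"),
    ).to_csv(metadata_path, sep="\t")


def write_panel(panel: GenePanel, path) -> None:
    """Write a gene panel as TSV with columns gene, probes, direction."""
    if len(panel) == 0:
        raise ValueError("refusing to write an empty panel")
    rows = [
        {
            "gene": g,
            "probes": ",".join(panel.probes.get(g, [])),
            "direction": panel.direction.get(g, ""),
        }
        for g in panel.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path) -> GenePanel:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genes = df["gene"].tolist()
    probes = {
        g: ([] if p == "" else p.split(","))
        for g, p in zip(genes, df["probes"])
    }
    direction = dict(zip(genes, df["direction"]))
    return GenePanel(genes=genes, probes=probes, direction=direction)


def subset_probes(study: ExpressionStudy, probe_ids) -> ExpressionStudy:
    """Row-subset a study to ``probe_ids`` in the requested order."""
    index = {p: i for i, p in enumerate(study.probe_ids)}
    try:
        rows = [index[p] for p in probe_ids]
    except KeyError as exc:
        raise KeyError(f"unknown probe id {exc.args[0]!r}") from None
    return ExpressionStudy(
        matrix=study.matrix[rows],
        probe_ids=[study.probe_ids[i] for i in rows],
        gene_symbols=[study.gene_symbols[i] for i in rows],
        sample_ids=list(study.sample_ids),
        group=list(study.group),
        batch=list(study.batch),
    )
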