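"""Core in-memory containers shared by every pipeline stage.

All tabular data is held in pandas objects wrapped in light dataclasses that
validate the domain invariants once, at construction.  Downstream modules
consume these types only; file parsing lives in :mod:`mgscope.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneCountMatrix",
    "FeatureTable",
    "SampleMetadata",
    "HitTable",
    "PathwayHierarchy",
    "CAG",
    "MGSCatalog",
    "ValidationError",
]

#: variables recognised as clinical measurements, with their unit classes
CLINICAL_CLASSES = {
    "TG": "metabolic",
    "TC": "metabolic",
    "FPG": "metabolic",
    "LH": "sex_hormone",
    "FSH": "sex_hormone",
    "LH/FSH": "sex_hormone",
    "E2": "sex_hormone",
    "PRL": "sex_hormone",
    "T": "sex_hormone",
    "PYY": "gut_brain",
    "ghrelin": "gut_brain",
    "acetic_acid": "SCFA",
    "propionic_acid": "SCFA",
    "butyric_acid": "SCFA",
    "valeric_acid": "SCFA",
}


class ValidationError(ValueError):
    """Raised when a container invariant is violated; names the offender."""


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dup = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


@dataclass
class GeneCountMatrix:
    """Mapped-read counts per gene and sample, with gene lengths.

    ``counts`` is genes x samples; ``lengths`` is per-gene nucleotide length
    aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene id")
        _check_unique(self.counts.columns, "sample id")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise ValidationError(f"genes missing a length: {missing[:5].tolist()}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValidationError(f"non-positive length for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()


@dataclass
class FeatureTable:
    """Non-negative feature x sample abundances.

    ``kind`` tags the semantics: raw ``count``, length-normalised
    ``copy_number``, or ``relative`` (each sample column sums to one).
    """

    values: pd.DataFrame
    kind: str = "count"

    _KINDS = ("count", "copy_number", "relative")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown kind {self.kind!r}; expected {self._KINDS}")
        _check_unique(self.values.index, "feature id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            f, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at feature {self.values.index[f]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.kind == "relative":
            sums = arr.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
            if len(bad):
                raise ValidationError(
                    f"relative table column {self.values.columns[bad[0]]!r} "
                    f"sums to {sums[bad[0]]!r}, expected 1"
                )

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class SampleMetadata:
    """Per-sample design and clinical variables.

    ``table`` is indexed by sample id with columns ``subject_id``, ``group``,
    ``timepoint`` plus any number of clinical variables (NaN = not measured).
    """

    table: pd.DataFrame
    group_levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample id")
        for col in ("subject_id", "group", "timepoint"):
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        if not self.group_levels:
            self.group_levels = tuple(pd.unique(self.table["group"]).tolist())
        else:
            extra = set(self.table["group"]) - set(self.group_levels)
            if extra:
                raise ValidationError(f"group labels outside declared levels: {extra}")
        clin = self.clinical_variables
        vals = self.table[clin].to_numpy(dtype=float) if clin else np.empty((0, 0))
        if vals.size and np.isinf(vals).any():
            raise ValidationError("non-finite clinical value")

    @property
    def clinical_variables(self) -> list[str]:
        reserved = {"subject_id", "group", "timepoint"}
        return [c for c in self.table.columns if c not in reserved]

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()


@dataclass
class HitTable:
    """Tabular alignment hits (BLAST outfmt-6 dialect plus derived coverage).

    Columns: gene_id, subject_id, taxon_label, identity (%), coverage
    (% of gene length aligned), bit_score, e_value.
    """

    rows: pd.DataFrame

    REQUIRED = ("gene_id", "subject_id", "identity", "coverage", "bit_score", "e_value")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.rows.columns:
                raise ValidationError(f"hit table missing column {col!r}")
        if "taxon_label" not in self.rows.columns:
            self.rows = self.rows.assign(taxon_label="")
        for col, lo, hi in (("identity", 0, 100), ("coverage", 0, 100)):
            v = self.rows[col].to_numpy(dtype=float)
            out = np.where((v < lo) | (v > hi))[0]
            if len(out):
                raise ValidationError(
                    f"{col} out of [{lo},{hi}] in row {out[0]} "
                    f"(gene {self.rows['gene_id'].iloc[out[0]]!r}: {v[out[0]]})"
                )
        if (self.rows["e_value"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative e-value in hit table")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class PathwayHierarchy:
    """pathway id -> (display name, level-2 parent label, member KO set)."""

    pathways: dict[str, tuple[str, str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (_, _, kos) in self.pathways.items():
            if not kos:
                raise ValidationError(f"pathway {pid!r} has no member KOs")

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][2]

    @property
    def all_kos(self) -> frozenset[str]:
        out: set[str] = set()
        for _, _, kos in self.pathways.values():
            out |= kos
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)


@dataclass
class CAG:
    """A co-abundance gene group: genes whose profiles co-vary across samples."""

    cag_id: str
    member_gene_ids: frozenset[str]
    profile: pd.Series  # per-sample median of member copy-number profiles

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 1:
            raise ValidationError(f"CAG {self.cag_id!r} has no members")

    @property
    def n_members(self) -> int:
        return len(self.member_gene_ids)


@dataclass
class MGSCatalog:
    """Ordered CAG list with MGS flags and optional per-MGS taxonomy.

    A CAG is an MGS when it has more than ``min_mgs_size`` member genes
    (strict inequality).  ``taxonomy`` maps cag_id -> dict with keys
    ``assigned_genome``, ``assigned_taxon``, ``rank`` (values may be None).
    """

    cags: list[CAG]
    min_mgs_size: int = 50
    taxonomy: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cag in self.cags:
            overlap = seen & cag.member_gene_ids
            if overlap:
                raise ValidationError(
                    f"gene(s) in multiple CAGs: {sorted(overlap)[:5]}"
                )
            seen |= cag.member_gene_ids
        non_mgs = set(self.taxonomy) - {c.cag_id for c in self.cags if self.is_mgs(c)}
        if non_mgs:
            raise ValidationError(f"taxonomy attached to non-MGS CAGs: {sorted(non_mgs)}")

    def is_mgs(self, cag: CAG) -> bool:
        return cag.n_members > self.min_mgs_size

    @property
    def mgs(self) -> list[CAG]:
        return [c for c in self.cags if self.is_mgs(c)]

    def __len__(self) -> int:
        return len(self.cags)
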