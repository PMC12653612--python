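"""Reading and writing genome summary tables.

The tables are the tab-separated summaries exported by the NCBI ``datasets``
tool: one row per assembly with the total gene count, the protein-coding and
pseudogene counts, and the total sequence length.  The non-coding gene count
is not a column of its own; it is derived as

    non-coding = total - protein-coding - pseudogenes

which is the identity every downstream computation in this package relies on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Domain",
    "GenomeRecord",
    "ReadReport",
    "read_genome_table",
    "write_genome_table",
]


class Domain(str, enum.Enum):
    """Domain-of-life label attached to a genome (optional metadata)."""

    BACTERIA = "Bacteria"
    ARCHAEA = "Archaea"
    EUKARYOTA = "Eukaryota"
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value: object) -> "Domain":
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        for member in cls:
            if member.value.lower() == text:
                return member
        return cls.UNKNOWN


@dataclass(frozen=True)
class GenomeRecord:
    """One sequenced genome: identity, gene counts, and sequence length.

    ``nc_genes`` is always the derived quantity ``total - pc - ps``; it is
    stored rather than recomputed so that records round-trip exactly through
    the table format.
    """

    assembly_name: str
    organism_name: str
    total_genes: int
    pc_genes: int
    ps_genes: int
    nc_genes: int
    size_bp: int
    domain: Domain = Domain.UNKNOWN

    def __post_init__(self) -> None:
        if self.total_genes < 0 or self.pc_genes < 0 or self.ps_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if self.pc_genes + self.ps_genes > self.total_genes:
            raise ValueError(
                f"pc + ps genes ({self.pc_genes + self.ps_genes}) exceed "
                f"total genes ({self.total_genes}) for {self.assembly_name!r}"
            )
        if self.nc_genes != self.total_genes - self.pc_genes - self.ps_genes:
            raise ValueError("nc_genes must equal total - pc - ps")
        if self.size_bp < 1:
            raise ValueError("size_bp must be positive")

    @classmethod
    def build(
        cls,
        assembly_name: str,
        organism_name: str,
        total_genes: int,
        pc_genes: int,
        ps_genes: int,
        size_bp: int,
        domain: Domain | str = Domain.UNKNOWN,
    ) -> "GenomeRecord":
        """Construct a record, deriving the non-coding count."""
        return cls(
            assembly_name=assembly_name,
            organism_name=organism_name,
            total_genes=int(total_genes),
            pc_genes=int(pc_genes),
            ps_genes=int(ps_genes),
            nc_genes=int(total_genes) - int(pc_genes) - int(ps_genes),
            size_bp=int(size_bp),
            domain=Domain.coerce(domain),
        )


# Canonical column names of the NCBI datasets summary dialect, plus the
# snake_case aliases of newer exports.  Matching is case-insensitive.
_COLUMNS = {
    "assembly_name": ("Assembly Name", "assembly_name"),
    "organism_name": ("Organism Name", "organism_name"),
    "size_bp": (
        "Assembly Stats Total Sequence Length",
        "assembly_stats_total_sequence_length",
        "total_sequence_length",
    ),
    "total_genes": ("Annotation Count Gene Total", "annotation_count_gene_total"),
    "pc_genes": (
        "Annotation Count Gene Protein-coding",
        "annotation_count_gene_protein_coding",
    ),
    "ps_genes": ("Annotation Count Gene Pseudogene", "annotation_count_gene_pseudogene"),
}
_DOMAIN_ALIASES = ("Domain", "domain")

# Header written by write_genome_table (the original dialect).
_CANONICAL_HEADER = [
    "Assembly Name",
    "Organism Name",
    "Assembly Stats Total Sequence Length",
    "Annotation Count Gene Total",
    "Annotation Count Gene Protein-coding",
    "Annotation Count Gene Pseudogene",
    "Domain",
]


@dataclass
class ReadReport:
    """Accounting of rows dropped while reading in lenient mode."""

    n_read: int = 0
    n_kept: int = 0
    dropped_invalid_counts: int = 0
    dropped_missing_fields: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.dropped_invalid_counts + self.dropped_missing_fields


def _resolve_columns(header: Sequence[str]) -> dict[str, str]:
    lower = {str(h).strip().lower(): h for h in header}
    resolved: dict[str, str] = {}
    for key, aliases in _COLUMNS.items():
        for alias in aliases:
            if alias.lower() in lower:
                resolved[key] = lower[alias.lower()]
                break
        else:
            raise ValueError(
                f"genome table is missing the mandatory column "
                f"{aliases[0]!r} (or an accepted alias)"
            )
    for alias in _DOMAIN_ALIASES:
        if alias.lower() in lower:
            resolved["domain"] = lower[alias.lower()]
            break
    return resolved


def read_genome_table(
    path: str | Path, strict: bool = False
) -> tuple[list[GenomeRecord], ReadReport]:
    """Read a tab-separated genome summary table.

    Parameters
    ----------
    path:
        TSV file with one header row containing the NCBI summary columns.
    strict:
        If true, any invalid row aborts the read with ``ValueError``;
        otherwise invalid rows are dropped and counted in the report.

    Returns
    -------
    (records, report):
        Valid records with the non-coding count derived, and a
        :class:`ReadReport` of what was dropped.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    columns = _resolve_columns(frame.columns)

    report = ReadReport(n_read=len(frame))
    records: list[GenomeRecord] = []
    for idx, row in frame.iterrows():
        raw = {key: row[col] for key, col in columns.items()}
        try:
            total = int(raw["total_genes"])
            pc = int(raw["pc_genes"])
            ps = int(raw["ps_genes"])
            size = int(raw["size_bp"])
        except (TypeError, ValueError):
            msg = f"row {idx}: missing or non-integer annotation counts"
            if strict:
                raise ValueError(msg) from None
            report.dropped_missing_fields += 1
            report.messages.append(msg)
            continue
        try:
            record = GenomeRecord.build(
                assembly_name=raw["assembly_name"],
                organism_name=raw["organism_name"],
                total_genes=total,
                pc_genes=pc,
                ps_genes=ps,
                size_bp=size,
                domain=raw.get("domain", Domain.UNKNOWN),
            )
        except ValueError as exc:
            msg = f"row {idx}: {exc}"
            if strict:
                raise ValueError(msg) from None
            report.dropped_invalid_counts += 1
            report.messages.append(msg)
            continue
        records.append(record)
    report.n_kept = len(records)
    return records, report


def write_genome_table(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records as a tab-separated table in the NCBI summary dialect.

    ``read_genome_table(write_genome_table(x))`` reproduces all fields
    exactly; the derived non-coding count is implied by the stored columns.
    """
    rows = [
        {
            "Assembly Name": r.assembly_name,
            "Organism Name": r.organism_name,
            "Assembly Stats Total Sequence Length": r.size_bp,
            "Annotation Count Gene Total": r.total_genes,
            "Annotation Count Gene Protein-coding": r.pc_genes,
            "Annotation Count Gene Pseudogene": r.ps_genes,
            "Domain": r.domain.value,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=_CANONICAL_HEADER)
    frame.to_csv(path, sep="\t", index=False)
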