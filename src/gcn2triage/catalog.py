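"""Variant catalog: data model, notation parsing and domain annotation for GCN2.

GCN2 (gene *EIF2AK4*) is a 1649-residue serine/threonine kinase whose
missense variants are implicated in pulmonary arterial hypertension (PAH)
and its biallelic-recessive subtypes PVOD and PCH.  The packaged fixture
(``data/catalog.tsv``) holds the published catalog of 34 natural missense
variants plus the engineered kinase-dead K619R control, together with six
in-silico predictor scores per variant and, for the 16 experimentally
tested variants (and the control), the summarised functional-assay panel.

Coordinates follow the printed convention: protein positions are 1-based
residue indices, cDNA positions are 1-based on the coding sequence, and
the single splice-region entry ("145-2A>G") carries a signed intron
offset and is exempt from the codon-consistency check.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .assays import AssayPanel, ExpressionSummary
from .insilico import PredictorProfile

__all__ = [
    "GCN2_LENGTH",
    "DOMAINS",
    "ProteinChange",
    "CdnaChange",
    "VariantRecord",
    "DomainLabel",
    "CatalogEntry",
    "Catalog",
    "CatalogError",
    "parse_variant_notation",
    "annotate_domain",
    "classify_rarity",
    "load_catalog",
]

GCN2_LENGTH = 1649

#: Closed residue spans of the annotated GCN2 domains.
DOMAINS: tuple[tuple[str, int, int], ...] = (
    ("RWD", 20, 137),
    ("pseudokinase", 276, 539),
    ("kinase", 585, 1016),
    ("HisRS-like", 1058, 1490),
    ("CTD", 1533, 1649),
)

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_NT = set("ACGT")

RARITY_RARE_BELOW = 0.01
RARITY_COMMON_ABOVE = 0.1


class CatalogError(ValueError):
    """Raised for malformed notation, invariant violations or bad fixtures."""


@dataclass(frozen=True)
class ProteinChange:
    """A single amino-acid substitution, e.g. R585Q."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in _AA or self.alt_aa not in _AA:
            raise CatalogError(f"invalid amino acid in {self.ref_aa}{self.position}{self.alt_aa}")
        if self.ref_aa == self.alt_aa:
            raise CatalogError(f"reference equals alternate amino acid at {self.position}")
        if not 1 <= self.position <= GCN2_LENGTH:
            raise CatalogError(f"residue {self.position} outside 1..{GCN2_LENGTH}")

    @classmethod
    def parse(cls, text: str) -> "ProteinChange":
        m = re.fullmatch(r"\s*([A-Z])\s*(\d+)\s*([A-Z])\s*", text or "")
        if not m:
            raise CatalogError(f"malformed protein change: {text!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class CdnaChange:
    """A coding-sequence substitution, e.g. 1754G>A, or a splice-region
    substitution with a signed intron offset, e.g. 145-2A>G."""

    position: int
    ref_base: str
    alt_base: str
    intron_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_base not in _NT or self.alt_base not in _NT:
            raise CatalogError(f"invalid nucleotide in cDNA change at {self.position}")
        if self.ref_base == self.alt_base:
            raise CatalogError(f"reference equals alternate base at c.{self.position}")
        if self.position < 1:
            raise CatalogError(f"cDNA position {self.position} must be >= 1")
        if self.intron_offset == 0:
            raise CatalogError("intron offset of 0 is not a valid splice-region notation")

    @property
    def codon(self) -> int:
        """1-based codon index implied by the cDNA position."""
        return math.ceil(self.position / 3)

    @classmethod
    def parse(cls, text: str) -> "CdnaChange":
        m = re.fullmatch(
            r"\s*(\d+)\s*([+-]\d+)?\s*([A-Z])\s*>\s*([A-Z])\s*", text or ""
        )
        if not m:
            raise CatalogError(f"malformed cDNA change: {text!r}")
        offset = int(m.group(2)) if m.group(2) else None
        return cls(int(m.group(1)), m.group(3), m.group(4), offset)

    def __str__(self) -> str:
        off = f"{self.intron_offset:+d}" if self.intron_offset is not None else ""
        return f"{self.position}{off}{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class DomainLabel:
    """A GCN2 domain name with its closed residue span; linker regions
    between domains are labelled ``interdomain``."""

    name: str
    start: int
    end: int

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class VariantRecord:
    """Identity, genetics and clinical context of one catalog variant."""

    protein: ProteinChange
    cdna: Optional[CdnaChange]
    diagnosis: str
    clinvar_class: Optional[str]  # None for the engineered control
    rarity: str  # rare / intermediate / common
    tested: bool
    control: bool = False

    def __post_init__(self) -> None:
        if self.control and self.clinvar_class is not None:
            raise CatalogError("engineered control carries no ClinVar class")
        if self.rarity not in {"rare", "intermediate", "common", "."}:
            raise CatalogError(f"unknown rarity class {self.rarity!r}")

    @property
    def name(self) -> str:
        return str(self.protein)

    @property
    def domain(self) -> DomainLabel:
        return annotate_domain(self.protein.position)


@dataclass
class CatalogEntry:
    """One catalog row: variant record, predictor profile and, for tested
    variants, the assay panel plus the printed reference calls."""

    record: VariantRecord
    profile: PredictorProfile
    panel: Optional[AssayPanel] = None
    insilico_printed: Optional[str] = None
    classification_printed: Optional[str] = None

    @property
    def name(self) -> str:
        return self.record.name


def parse_variant_notation(cdna_text: str, protein_text: str) -> tuple[CdnaChange, ProteinChange]:
    """Parse a paired cDNA/protein notation and cross-check the coordinates.

    For coding substitutions the codon implied by the cDNA position,
    ``ceil(pos/3)``, must equal the protein residue index; splice-region
    entries (those with an intron offset) are exempt because the protein
    label then describes the predicted downstream consequence.
    """
    if not cdna_text or not protein_text:
        raise CatalogError("empty variant notation")
    cdna = CdnaChange.parse(cdna_text)
    protein = ProteinChange.parse(protein_text)
    if cdna.intron_offset is None and cdna.codon != protein.position:
        raise CatalogError(
            f"cDNA position {cdna.position} (codon {cdna.codon}) is inconsistent "
            f"with protein residue {protein.position}"
        )
    return cdna, protein


def annotate_domain(position: int) -> DomainLabel:
    """Map a residue index to the unique GCN2 domain containing it."""
    if not 1 <= position <= GCN2_LENGTH:
        raise CatalogError(f"residue {position} outside 1..{GCN2_LENGTH}")
    for name, start, end in DOMAINS:
        if start <= position <= end:
            return DomainLabel(name, start, end)
    return DomainLabel("interdomain", 1, GCN2_LENGTH)


def classify_rarity(allele_frequency: float) -> str:
    """Categorise a population allele frequency.

    Strictly below 0.01 is ``rare``, strictly above 0.1 is ``common``
    (the three common polymorphisms I441L, E556G and G1306C), and the
    closed band in between is ``intermediate``.
    """
    if not math.isfinite(allele_frequency) or not 0 <= allele_frequency <= 1:
        raise CatalogError(f"allele frequency {allele_frequency!r} outside [0, 1]")
    if allele_frequency < RARITY_RARE_BELOW:
        return "rare"
    if allele_frequency > RARITY_COMMON_ABOVE:
        return "common"
    return "intermediate"


class Catalog:
    """An ordered, validated collection of catalog entries."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self.entries: list[CatalogEntry] = list(entries)
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise CatalogError(f"duplicate variants in catalog: {sorted(dupes)}")
        n_controls = sum(e.record.control for e in self.entries)
        if self.entries and n_controls != 1:
            raise CatalogError(f"expected exactly one engineered control, found {n_controls}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> CatalogEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def natural(self) -> list[CatalogEntry]:
        return [e for e in self.entries if not e.record.control]

    @property
    def tested(self) -> list[CatalogEntry]:
        """The 16-variant experimental panel (control excluded)."""
        return [e for e in self.entries if e.record.tested and not e.record.control]

    @property
    def assayed(self) -> list[CatalogEntry]:
        """All entries with an assay panel (tested panel + control)."""
        return [e for e in self.entries if e.panel is not None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            r = e.record
            p = e.profile
            row = {
                "variant": e.name,
                "cdna": str(r.cdna) if r.cdna else None,
                "position": r.protein.position,
                "domain": r.domain.name,
                "clinvar_class": r.clinvar_class,
                "diagnosis": r.diagnosis,
                "rarity": r.rarity,
                "tested": r.tested,
                "control": r.control,
                "sift": p.sift_call,
                "polyphen2": p.polyphen2,
                "cadd": p.cadd_phred,
                "revel": p.revel,
                "alphamissense": p.alphamissense,
                "foldx_ddg": p.foldx_ddg,
                "insilico_printed": e.insilico_printed,
                "classification_printed": e.classification_printed,
            }
            if e.panel is not None:
                row.update(
                    induction=e.panel.induction,
                    expression_ratio=e.panel.expression.ratio_vs_wt,
                    expression_reduced=e.panel.expression.significantly_reduced,
                    expression_severe=e.panel.expression.severe,
                    autophos_t899=e.panel.autophos_t899,
                    dimerisation=e.panel.dimerisation,
                    eif2a_phos_pct=e.panel.eif2a_phos_pct,
                    rescue_gcn2ib=e.panel.rescue_gcn2ib,
                    context_null_second_allele=e.panel.context_null_second_allele,
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        recs = [e.record for e in self.natural]
        return {
            "n_total": len(self.entries),
            "n_natural": len(recs),
            "n_control": len(self.entries) - len(recs),
            "n_pathogenic": sum(r.clinvar_class == "pathogenic/likely-pathogenic" for r in recs),
            "n_benign": sum(r.clinvar_class == "benign/likely-benign" for r in recs),
            "n_vus": sum(r.clinvar_class == "VUS" for r in recs),
            "n_common": sum(r.rarity == "common" for r in recs),
            "n_tested": sum(r.tested for r in recs),
        }


_REQUIRED_COLUMNS = [
    "variant", "cdna", "clinvar_class", "diagnosis", "rarity", "tested", "control",
    "sift", "polyphen2", "cadd", "revel", "alphamissense", "foldx_ddg",
    "insilico_printed", "induction", "expression_ratio", "expression_reduced",
    "autophos_t899", "dimerisation", "eif2a_phos_pct", "rescue_gcn2ib",
    "context_null_second_allele", "classification",
]


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == "."


def _as_bool(value, where: str) -> bool:
    if isinstance(value, bool):
        return value
    if str(value).lower() in {"true", "1", "yes"}:
        return True
    if str(value).lower() in {"false", "0", "no"}:
        return False
    raise CatalogError(f"{where}: cannot interpret {value!r} as boolean")


def packaged_fixture_path() -> Path:
    """Filesystem path of the packaged catalog fixture."""
    return Path(str(resources.files("gcn2triage").joinpath("data/catalog.tsv")))


def load_catalog(path: str | Path | None = None, severe_threshold: float | None = None) -> Catalog:
    """Load and validate a catalog table (the packaged fixture by default).

    The table is tab-delimited UTF-8 with ``.`` for missing values; the
    expected header is the one documented in ``data/catalog.tsv``.  Rows of
    the experimental panel carry summarised assay readouts; the ``severe``
    expression flag is derived from the printed ratio via the configured
    threshold (default taken from :mod:`gcn2triage.config`).
    """
    from .config import DEFAULT_THRESHOLDS

    if severe_threshold is None:
        severe_threshold = DEFAULT_THRESHOLDS.severe_expression
    if path is None:
        path = packaged_fixture_path()
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"catalog file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as err:
        raise CatalogError(f"catalog file {path} is empty") from err
    if df.empty:
        raise CatalogError(f"catalog file {path} contains no rows")
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CatalogError(f"catalog file {path} missing columns: {missing_cols}")

    entries = []
    for idx, row in df.iterrows():
        where = f"{path.name} row {idx + 2} ({row['variant']})"
        try:
            protein = ProteinChange.parse(row["variant"])
            if _missing(row["cdna"]):
                cdna = None
            else:
                cdna, protein = parse_variant_notation(row["cdna"], row["variant"])
            record = VariantRecord(
                protein=protein,
                cdna=cdna,
                diagnosis=row["diagnosis"],
                clinvar_class=None if _missing(row["clinvar_class"]) else row["clinvar_class"],
                rarity=row["rarity"] if not _missing(row["rarity"]) else ".",
                tested=_as_bool(row["tested"], where),
                control=_as_bool(row["control"], where),
            )
            profile = PredictorProfile(
                sift_call=row["sift"],
                polyphen2=float(row["polyphen2"]),
                cadd_phred=float(row["cadd"]),
                revel=float(row["revel"]),
                alphamissense=float(row["alphamissense"]),
                foldx_ddg=float(row["foldx_ddg"]),
            )
            panel = None
            if not _missing(row["induction"]):
                ratio = float(row["expression_ratio"])
                reduced = _as_bool(row["expression_reduced"], where)
                expression = ExpressionSummary(
                    ratio_vs_wt=ratio,
                    significantly_reduced=reduced,
                    severe=reduced and ratio < severe_threshold,
                )
                panel = AssayPanel(
                    induction=row["induction"],
                    expression=expression,
                    autophos_t899=row["autophos_t899"],
                    dimerisation="untested" if _missing(row["dimerisation"]) else row["dimerisation"],
                    eif2a_phos_pct=None if _missing(row["eif2a_phos_pct"]) else float(row["eif2a_phos_pct"]),
                    rescue_gcn2ib="untested" if _missing(row["rescue_gcn2ib"]) else row["rescue_gcn2ib"],
                    context_null_second_allele=_as_bool(row["context_null_second_allele"], where),
                )
            elif _as_bool(row["tested"], where):
                raise CatalogError("tested variant lacks assay readouts")
            entries.append(
                CatalogEntry(
                    record=record,
                    profile=profile,
                    panel=panel,
                    insilico_printed=None if _missing(row["insilico_printed"]) else row["insilico_printed"],
                    classification_printed=None if _missing(row["classification"]) else row["classification"],
                )
            )
        except CatalogError as err:
            raise CatalogError(f"{where}: {err}") from err
        except (KeyError, ValueError) as err:
            raise CatalogError(f"{where}: {err}") from err
    return Catalog(entries)
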