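"""KO annotation tables, strain gene tables, and per-KO essentiality tallies.

A KO (KEGG Ortholog) groups genes by molecular function across organisms.
Training data consist of per-strain gene tables (locus tag, KO, experimental
essentiality label, DEG-style) and a KO annotation table carrying the
"//"-joined KEGG pathway and COG annotation strings plus the reaction
identifiers (#R) that link functionally equivalent KOs. Tallying how often a
KO is essential, "missing essential" (recovered by pathway remapping), or
non-essential across the training strains feeds the experimental
essentiality score.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field

from .exceptions import FormatError, IntegrityError

logger = logging.getLogger(__name__)

#: Allowed experimental essentiality labels.
ESSENTIAL = "essential_experimental"
NONESSENTIAL = "nonessential"
UNKNOWN = "unknown"
LABELS = frozenset({ESSENTIAL, NONESSENTIAL, UNKNOWN})

_KO_RE = re.compile(r"^K\d{5}$")

_ANNOTATION_COLUMNS = [
    "ko_id",
    "kegg_pathway_annotation",
    "cog_annotation",
    "reaction_ids",
    "gene_name",
    "description",
]
_STRAIN_COLUMNS = ["locus_tag", "ko_id", "label"]


@dataclass(frozen=True)
class KOAnnotation:
    """Functional annotation attached to one KO.

    Annotation strings are stored verbatim: multi-pathway annotations stay as
    one "//"-joined string and grouping for P_score matches the whole string,
    never individual tokens (unless explicitly requested downstream).
    """

    ko_id: str
    kegg_pathway_annotation: str = ""
    cog_annotation: str = ""
    reaction_ids: frozenset[str] = field(default_factory=frozenset)
    gene_name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not _KO_RE.match(self.ko_id):
            raise FormatError(f"invalid KO identifier: {self.ko_id!r}")
        object.__setattr__(self, "reaction_ids", frozenset(self.reaction_ids))


@dataclass(frozen=True)
class StrainGeneRecord:
    """One gene of one strain: locus tag, optional KO, essentiality label."""

    strain_id: str
    locus_tag: str
    ko_id: str | None = None
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise FormatError(f"unknown essentiality label: {self.label!r}")
        if self.ko_id is not None and not _KO_RE.match(self.ko_id):
            raise FormatError(f"invalid KO identifier: {self.ko_id!r}")


@dataclass(frozen=True)
class EssentialityCounts:
    """Per-KO tallies over the training strains.

    ``eg_e`` counts strains where the KO is experimentally essential, ``eg_m``
    strains where it is called missing-essential by remapping, ``non_eg``
    strains where it appears but is neither. Each strain contributes one unit
    to at most one tally, so the three never exceed ``n_strains``.
    """

    ko_id: str
    eg_e: int = 0
    eg_m: int = 0
    non_eg: int = 0
    n_strains: int = 31

    def __post_init__(self) -> None:
        if min(self.eg_e, self.eg_m, self.non_eg) < 0:
            raise IntegrityError("tallies must be non-negative")
        if self.n_strains < 1:
            raise IntegrityError("n_strains must be >= 1")
        if self.eg_e + self.eg_m + self.non_eg > self.n_strains:
            raise IntegrityError(
                f"{self.ko_id}: tallies exceed strain count "
                f"({self.eg_e}+{self.eg_m}+{self.non_eg} > {self.n_strains})"
            )

    @property
    def appearances(self) -> int:
        return self.eg_e + self.eg_m + self.non_eg


def _read_tsv(path, required_columns):
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        missing = [c for c in required_columns if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        return list(reader)


def load_ko_annotations(path) -> dict[str, KOAnnotation]:
    """Load a KO annotation TSV into an ordered ``ko_id -> KOAnnotation`` map.

    Empty cells become empty strings (or an empty reaction set); a repeated
    ko_id is an integrity error.
    """
    table: dict[str, KOAnnotation] = {}
    for row in _read_tsv(path, _ANNOTATION_COLUMNS):
        ko_id = (row["ko_id"] or "").strip()
        if ko_id in table:
            raise IntegrityError(f"{path}: duplicate ko_id {ko_id}")
        reactions = frozenset(
            t for t in (row["reaction_ids"] or "").split("//") if t.strip()
        )
        table[ko_id] = KOAnnotation(
            ko_id=ko_id,
            kegg_pathway_annotation=row["kegg_pathway_annotation"] or "",
            cog_annotation=row["cog_annotation"] or "",
            reaction_ids=reactions,
            gene_name=row["gene_name"] or "",
            description=row["description"] or "",
        )
    return table


def write_ko_annotations(table: dict[str, KOAnnotation], path) -> None:
    """Serialize an annotation map back to the TSV dialect (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for ann in table.values():
            writer.writerow(
                [
                    ann.ko_id,
                    ann.kegg_pathway_annotation,
                    ann.cog_annotation,
                    "//".join(sorted(ann.reaction_ids)),
                    ann.gene_name,
                    ann.description,
                ]
            )


def load_strain_genes(path, strain_id: str) -> list[StrainGeneRecord]:
    """Load one strain's gene table (locus_tag, ko_id, label).

    A blank ko_id cell means the gene has no KO assignment. Labels outside
    {essential_experimental, nonessential, unknown} are a format error and a
    duplicate locus tag is an integrity error.
    """
    records: list[StrainGeneRecord] = []
    seen: set[str] = set()
    for row in _read_tsv(path, _STRAIN_COLUMNS):
        locus = (row["locus_tag"] or "").strip()
        if not locus:
            raise FormatError(f"{path}: blank locus_tag")
        if locus in seen:
            raise IntegrityError(f"{path}: duplicate locus_tag {locus}")
        seen.add(locus)
        ko = (row["ko_id"] or "").strip() or None
        records.append(
            StrainGeneRecord(
                strain_id=strain_id, locus_tag=locus, ko_id=ko, label=row["label"]
            )
        )
    return records


def write_strain_genes(records: list[StrainGeneRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_STRAIN_COLUMNS)
        for rec in records:
            writer.writerow([rec.locus_tag, rec.ko_id or "", rec.label])


def expand_by_reaction(
    ko_set: set[str], annotations: dict[str, KOAnnotation]
) -> set[str]:
    """Expand a KO set by one shared-reaction hop.

    Returns ``ko_set`` plus every annotated KO sharing at least one reaction
    identifier (#R) with a member of ``ko_set``. The expansion is single-hop:
    KOs only reachable through a newly added member are not pulled in by this
    call. KOs absent from the annotation table pass through untouched.
    """
    seed_reactions: set[str] = set()
    for ko in ko_set:
        ann = annotations.get(ko)
        if ann is not None:
            seed_reactions |= ann.reaction_ids
    if not seed_reactions:
        return set(ko_set)
    expanded = set(ko_set)
    for ko, ann in annotations.items():
        if ann.reaction_ids & seed_reactions:
            expanded.add(ko)
    return expanded


def tally_ko_essentiality(
    strain_tables: list[list[StrainGeneRecord]],
    remapped: dict[str, set[str]] | None = None,
) -> dict[str, EssentialityCounts]:
    """Tally per-KO essentiality over a panel of strain tables.

    Per strain, a KO is classified once, with precedence experimental-essential
    > missing-essential > non-essential: essential if any of its genes in the
    strain is labeled essential_experimental, else missing-essential if any of
    its genes is in ``remapped[strain_id]`` (locus tags the remapping search
    reclassified), else non-essential. Genes with unknown labels never enter
    the tallies.
    """
    remapped = remapped or {}
    n_strains = len(strain_tables)
    if n_strains == 0:
        raise IntegrityError("at least one strain table is required")

    strain_ids = []
    by_strain: dict[str, list[StrainGeneRecord]] = {}
    for table in strain_tables:
        if not table:
            continue
        sid = table[0].strain_id
        strain_ids.append(sid)
        by_strain[sid] = table
    for sid, tags in remapped.items():
        if sid not in by_strain:
            raise IntegrityError(f"remapped strain {sid!r} has no gene table")
        known = {rec.locus_tag for rec in by_strain[sid]}
        dangling = set(tags) - known
        if dangling:
            raise IntegrityError(
                f"remapped locus tags not in strain {sid}: {sorted(dangling)}"
            )

    counts: dict[str, list[int]] = {}  # ko -> [eg_e, eg_m, non_eg]
    for sid in strain_ids:
        missing_tags = remapped.get(sid, set())
        per_ko: dict[str, str] = {}
        for rec in by_strain[sid]:
            if rec.ko_id is None:
                continue
            if rec.label == UNKNOWN:
                logger.warning(
                    "strain %s gene %s: unknown label dropped from tallies",
                    sid,
                    rec.locus_tag,
                )
                continue
            if rec.label == ESSENTIAL:
                cls = "e"
            elif rec.locus_tag in missing_tags:
                cls = "m"
            else:
                cls = "n"
            prev = per_ko.get(rec.ko_id)
            order = {"e": 0, "m": 1, "n": 2}
            if prev is None or order[cls] < order[prev]:
                per_ko[rec.ko_id] = cls
        for ko, cls in per_ko.items():
            slot = counts.setdefault(ko, [0, 0, 0])
            slot[{"e": 0, "m": 1, "n": 2}[cls]] += 1

    return {
        ko: EssentialityCounts(
            ko_id=ko, eg_e=c[0], eg_m=c[1], non_eg=c[2], n_strains=n_strains
        )
        for ko, c in sorted(counts.items())
    }


_TALLY_COLUMNS = ["ko_id", "eg_e", "eg_m", "non_eg", "n_strains"]


def write_tallies(tallies: dict[str, EssentialityCounts], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_TALLY_COLUMNS)
        for t in tallies.values():
            writer.writerow([t.ko_id, t.eg_e, t.eg_m, t.non_eg, t.n_strains])


def load_tallies(path) -> dict[str, EssentialityCounts]:
    out: dict[str, EssentialityCounts] = {}
    for row in _read_tsv(path, _TALLY_COLUMNS):
        ko = row["ko_id"].strip()
        if ko in out:
            raise IntegrityError(f"{path}: duplicate ko_id {ko}")
        out[ko] = EssentialityCounts(
            ko_id=ko,
            eg_e=int(row["eg_e"]),
            eg_m=int(row["eg_m"]),
            non_eg=int(row["non_eg"]),
            n_strains=int(row["n_strains"]),
        )
    return out
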