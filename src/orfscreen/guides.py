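"""sgRNA library records, cut-site geometry and library filtering.

SpCas9 makes a blunt double-strand cut between protospacer positions 17 and
18 (counting from the PAM-distal end), i.e. 3 bp 5' of the PAM.  The recorded
``cut_site`` is the base immediately 5' of the cut on the protospacer strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomicInterval

__all__ = [
    "GuideRecord",
    "LibraryManifest",
    "compute_cut_site",
    "filter_guides",
    "load_library",
    "write_library",
]

GUIDE_CLASSES = ("targeting", "positive_control", "negative_control")

LIBRARY_COLUMNS = [
    "guide_id",
    "protospacer",
    "chrom",
    "start",
    "end",
    "strand",
    "pam_start",
    "class",
    "target_orf",
    "efficiency",
    "genome_hits",
]


@dataclass
class GuideRecord:
    guide_id: str
    protospacer: str
    chrom: str
    strand: str
    protospacer_interval: GenomicInterval
    pam_interval: GenomicInterval
    guide_class: str = "targeting"
    target_orf: str = ""
    efficiency: float = 1.0
    genome_hits: int = 1
    cut_site: int | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError(f"protospacer of {self.guide_id} must be 20 nt")
        if len(self.pam_interval) != 3:
            raise ValueError(f"PAM of {self.guide_id} must be 3 nt")
        if self.guide_class not in GUIDE_CLASSES:
            raise ValueError(f"unknown guide class {self.guide_class!r}")
        if self.cut_site is None:
            self.cut_site = compute_cut_site(self)


def compute_cut_site(guide: GuideRecord) -> int:
    """Genomic position of the base immediately 5' of the blunt cut.

    The cut falls between protospacer positions 17|18 (1-based from the
    PAM-distal end): plus strand -> ``interval.end - 4``, minus strand ->
    ``interval.start + 3``.
    """
    if guide.strand == "+":
        return guide.protospacer_interval.end - 4
    if guide.strand == "-":
        return guide.protospacer_interval.start + 3
    raise ValueError(f"guide {guide.guide_id} has no strand")


@dataclass
class LibraryManifest:
    guides: list[GuideRecord] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(GUIDE_CLASSES, 0)
        for g in self.guides:
            counts[g.guide_class] += 1
        return counts

    def by_class(self, guide_class: str) -> list[GuideRecord]:
        return [g for g in self.guides if g.guide_class == guide_class]


# exclusion rules, applied in a fixed order for logging; the kept set is
# order-independent because rejection is a disjunction
_RULES = (
    ("multi_mapping", lambda g: g.genome_hits > 1),
    ("contains_N", lambda g: "N" in g.protospacer.upper()),
    ("poly_T", lambda g: "TTTT" in g.protospacer.upper()),
    ("high_GC", lambda g: _gc_fraction(g.protospacer) > 0.60),
    ("low_efficiency", lambda g: g.efficiency < 0.2),
)


def _gc_fraction(protospacer: str) -> float:
    s = protospacer.upper()
    return (s.count("G") + s.count("C")) / len(s)


def filter_guides(
    guides: list[GuideRecord],
) -> tuple[list[GuideRecord], pd.DataFrame]:
    """Apply the four library exclusion rules.

    A guide is rejected if it maps to multiple genomic regions, contains any
    N or a run of four or more Ts, has GC fraction strictly above 0.60, or an
    efficiency score strictly below 0.2.  Returns the kept guides and a log
    with one row per rejected guide naming the first matching rule.
    """
    kept, log_rows = [], []
    for g in guides:
        if not re.fullmatch(r"[ACGTN]{20}", g.protospacer.upper()):
            raise ValueError(
                f"guide {g.guide_id}: protospacer has characters outside ACGTN"
            )
        for rule_name, rule in _RULES:
            if rule(g):
                log_rows.append((g.guide_id, rule_name))
                break
        else:
            kept.append(g)
    log = pd.DataFrame(log_rows, columns=["guide_id", "rule"])
    return kept, log


def load_library(tsv_path: str) -> LibraryManifest:
    """Read a library TSV (see ``LIBRARY_COLUMNS``) into a manifest."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library TSV missing columns: {sorted(missing)}")
    if df["guide_id"].duplicated().any():
        dups = df.loc[df["guide_id"].duplicated(), "guide_id"].tolist()
        raise ValueError(f"duplicate guide_id(s): {dups[:5]}")
    guides = []
    for row in df.to_dict("records"):
        pam_start = int(row["pam_start"])
        chrom, strand = str(row["chrom"]), str(row["strand"])
        guides.append(
            GuideRecord(
                guide_id=str(row["guide_id"]),
                protospacer=str(row["protospacer"]),
                chrom=chrom,
                strand=strand,
                protospacer_interval=GenomicInterval(
                    chrom, int(row["start"]), int(row["end"]), strand
                ),
                pam_interval=GenomicInterval(chrom, pam_start, pam_start + 3, strand),
                guide_class=str(row["class"]),
                target_orf=""
                if pd.isna(row["target_orf"])
                else str(row["target_orf"]),
                efficiency=float(row["efficiency"]),
                genome_hits=int(row["genome_hits"]),
            )
        )
    return LibraryManifest(guides=guides)


def write_library(path: str, manifest: LibraryManifest) -> None:
    rows = []
    for g in manifest.guides:
        rows.append(
            (
                g.guide_id,
                g.protospacer,
                g.chrom,
                g.protospacer_interval.start,
                g.protospacer_interval.end,
                g.strand,
                g.pam_interval.start,
                g.guide_class,
                g.target_orf,
                g.efficiency,
                g.genome_hits,
            )
        )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)
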