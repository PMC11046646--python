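"""Major-pilin sequence survey: class III signal-peptide detection and
cleavage, mature-length classification, identity-based redundancy filtering,
per-taxon statistics, and N-terminal consensus profiling.

Mature-sequence numbering starts at the Phe exposed by cleavage (F = residue
1), so the conserved Glu of the recognition motif is position 5 and the
conserved Pro is position 22.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PrepilinRecord",
    "SurveyConfig",
    "SurveySummary",
    "detect_spiii",
    "cleave",
    "classify_length",
    "pairwise_identity",
    "cluster_identity",
    "summarize_taxa",
    "consensus_profile",
    "read_fasta",
    "write_fasta",
    "read_taxonomy_tsv",
    "load_survey_table",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_HYDROPHOBIC_PLUS1 = set("FILMV")
_SCAN_WINDOW = 60  # motif must begin within the first 60 residues


@dataclass
class PrepilinRecord:
    id: str
    sequence: str = ""
    phylum: str = ""
    klass: str = ""
    spiii_cleavage: int | None = None     # 0-based index of the Gly
    spiii_strict: bool | None = None      # True when the +1 residue is Phe
    mature_length: int | None = None
    size_class: str | None = None         # large | standard

    @property
    def mature_sequence(self) -> str | None:
        if self.spiii_cleavage is None or not self.sequence:
            return None
        return self.sequence[self.spiii_cleavage + 1:]


@dataclass(frozen=True)
class SurveyConfig:
    large_threshold: int = 166
    identity_cutoff: float = 0.90
    consensus_cutoff: float = 0.60
    nterm_window: int = 55
    other_fraction: float = 0.01   # taxa below this share go to "other"

    def __post_init__(self) -> None:
        if self.large_threshold < 1:
            raise ValueError("large_threshold must be positive")
        for name in ("identity_cutoff", "consensus_cutoff"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class SurveySummary:
    n_total: int
    n_large: int
    pct_large: int            # nearest-integer percent
    length_mean: float
    length_sd: float           # population SD
    length_min: int
    length_max: int
    per_taxon: pd.DataFrame
    n_unclassified: int = 0


# ---------------------------------------------------------------------------
# Signal peptide detection / cleavage
# ---------------------------------------------------------------------------

def detect_spiii(seq: str, strict_only: bool = False) -> int | None:
    """0-based index of the Gly of the first G-[F]-x-x-x-E motif, or None.

    The scan covers motif starts within the first 60 residues. A strict pass
    requiring Phe at +1 runs first; unless `strict_only`, a fallback pass
    then admits the hydrophobic set {F, I, L, M, V} at +1.
    """
    seq = seq.upper()
    if len(seq) < 10:
        raise ValueError("sequence shorter than 10 residues")
    bad = set(seq) - _AA - {"X"}
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    limit = min(_SCAN_WINDOW, len(seq) - 6)
    for allowed in ((frozenset("F"),) if strict_only
                    else (frozenset("F"), frozenset(_HYDROPHOBIC_PLUS1))):
        for i in range(limit):
            if seq[i] == "G" and seq[i + 1] in allowed and seq[i + 5] == "E":
                return i
    return None


def cleave(record: PrepilinRecord, strict_only: bool = False) -> PrepilinRecord:
    """Locate the signal-peptide cleavage site and fill the derived fields."""
    idx = detect_spiii(record.sequence, strict_only=strict_only)
    record.spiii_cleavage = idx
    if idx is not None:
        record.spiii_strict = record.sequence[idx + 1].upper() == "F"
        record.mature_length = len(record.sequence) - (idx + 1)
    return record


def classify_length(record: PrepilinRecord,
                    cfg: SurveyConfig = SurveyConfig()) -> PrepilinRecord:
    """Set size_class to large iff mature_length >= cfg.large_threshold."""
    if record.mature_length is None:
        if record.spiii_cleavage is None and record.sequence:
            record.size_class = None
            return record
        if record.spiii_cleavage is not None:
            record.mature_length = len(record.sequence) - (record.spiii_cleavage + 1)
    if record.mature_length is None:
        record.size_class = None
        return record
    record.size_class = ("large" if record.mature_length >= cfg.large_threshold
                         else "standard")
    return record


# ---------------------------------------------------------------------------
# Redundancy filtering
# ---------------------------------------------------------------------------

def _aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Global-alignment identity: matches / alignment columns (incl. gaps)."""
    if seq_a == seq_b:
        return 1.0
    if aligner is None:
        aligner = _aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def cluster_identity(records: list[PrepilinRecord], cutoff: float = 0.90,
                     ) -> tuple[list[PrepilinRecord], dict[str, str]]:
    """Greedy representative clustering at the given identity cutoff.

    Sequences are visited longest-first (ties broken by id); each joins the
    first retained representative with identity strictly above `cutoff`,
    otherwise it becomes a representative itself. Returns (representatives,
    member id -> representative id map). Idempotent on its own output.
    """
    if not records:
        raise ValueError("no records to cluster")
    aligner = _aligner()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[PrepilinRecord] = []
    assignment: dict[str, str] = {}
    for rec in ordered:
        home = None
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence, aligner) > cutoff:
                home = rep
                break
        if home is None:
            reps.append(rec)
            assignment[rec.id] = rec.id
        else:
            assignment[rec.id] = home.id
    return reps, assignment


# ---------------------------------------------------------------------------
# Taxon statistics
# ---------------------------------------------------------------------------

def _stats_block(lengths: np.ndarray, n_large: int) -> dict:
    return {
        "n": int(len(lengths)),
        "n_large": int(n_large),
        "pct_large": int(round(100.0 * n_large / len(lengths))),
        "length_mean": float(lengths.mean()),
        "length_sd": float(lengths.std()),   # population SD
        "length_min": int(lengths.min()),
        "length_max": int(lengths.max()),
    }


def summarize_taxa(records: list[PrepilinRecord],
                   cfg: SurveyConfig = SurveyConfig()) -> SurveySummary:
    """Global and per-taxon length statistics and large-pilin fractions.

    Records without a size class are excluded from statistics but counted.
    Taxa holding less than `cfg.other_fraction` of classified records are
    pooled into an "other" row, separately at the phylum and class levels.
    """
    classified = [r for r in records if r.size_class is not None
                  and r.mature_length is not None]
    n_unclassified = len(records) - len(classified)
    if n_unclassified:
        logger.info("summarize_taxa: %d records dropped (no size class)",
                    n_unclassified)
    if not classified:
        raise ValueError("no classified records to summarize")
    lengths = np.array([r.mature_length for r in classified])
    n_large = sum(r.size_class == "large" for r in classified)

    rows = []
    threshold = cfg.other_fraction * len(classified)
    for level, key in (("phylum", lambda r: r.phylum),
                       ("class", lambda r: r.klass)):
        groups: dict[str, list[PrepilinRecord]] = {}
        for r in classified:
            name = key(r) or "unassigned"
            groups.setdefault(name, []).append(r)
        other: list[PrepilinRecord] = []
        for name, members in sorted(groups.items()):
            if len(members) < threshold:
                other.extend(members)
                continue
            mlen = np.array([m.mature_length for m in members])
            rows.append({"level": level, "taxon": name,
                         **_stats_block(mlen, sum(m.size_class == "large"
                                                  for m in members))})
        if other:
            mlen = np.array([m.mature_length for m in other])
            rows.append({"level": level, "taxon": "other",
                         **_stats_block(mlen, sum(m.size_class == "large"
                                                  for m in other))})
    per_taxon = pd.DataFrame(rows)
    g = _stats_block(lengths, n_large)
    return SurveySummary(n_total=len(classified), n_large=g["n_large"],
                         pct_large=g["pct_large"],
                         length_mean=g["length_mean"],
                         length_sd=g["length_sd"],
                         length_min=g["length_min"],
                         length_max=g["length_max"],
                         per_taxon=per_taxon,
                         n_unclassified=n_unclassified)


# ---------------------------------------------------------------------------
# Consensus profiling
# ---------------------------------------------------------------------------

def consensus_profile(records: list[PrepilinRecord],
                      cfg: SurveyConfig = SurveyConfig()) -> pd.DataFrame:
    """Positional consensus over mature N-termini (position 1 = the Phe).

    Ungapped stacking over the first `cfg.nterm_window` positions: each row
    reports the modal residue, its frequency among sequences covering that
    position, and a conserved flag at `cfg.consensus_cutoff`.
    """
    columns: list[Counter] = [Counter() for _ in range(cfg.nterm_window)]
    n_used = 0
    for rec in records:
        mature = rec.mature_sequence
        if not mature:
            continue
        n_used += 1
        for pos, residue in enumerate(mature[:cfg.nterm_window]):
            columns[pos][residue] += 1
    if n_used == 0:
        raise ValueError("no records with mature sequences")
    rows = []
    for pos, counter in enumerate(columns, start=1):
        coverage = sum(counter.values())
        if coverage == 0:
            continue
        residue, count = counter.most_common(1)[0]
        freq = count / coverage
        rows.append({"position": pos, "residue": residue,
                     "frequency": freq, "coverage": coverage,
                     "conserved": freq >= cfg.consensus_cutoff})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[PrepilinRecord]:
    from Bio import SeqIO

    records = [PrepilinRecord(id=rec.id, sequence=str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[PrepilinRecord], path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                handle.write(rec.sequence[i:i + 60] + "\n")


def read_taxonomy_tsv(path) -> dict[str, tuple[str, str]]:
    """TSV sidecar with columns id, phylum, class."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = {c.lower(): c for c in df.columns}
    out = {}
    for _, row in df.iterrows():
        out[row[cols["id"]]] = (row[cols.get("phylum", "phylum")],
                                row[cols.get("class", "class")])
    return out


def attach_taxonomy(records: list[PrepilinRecord],
                    taxonomy: dict[str, tuple[str, str]]) -> int:
    """Annotate records in place; returns the number of ids not found."""
    missing = 0
    for rec in records:
        if rec.id in taxonomy:
            rec.phylum, rec.klass = taxonomy[rec.id]
        else:
            missing += 1
    return missing


def load_survey_table(path) -> list[PrepilinRecord]:
    """Ingest a curated survey table (XLSX or TSV).

    Column names are matched case-insensitively; recognized keys are an id
    column, a sequence and/or mature-length column, and phylum/class
    columns. When only mature lengths ship, sequence-level operations are
    skipped downstream with a logged notice.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    rename: dict[str, str] = {}
    for col in df.columns:
        low = str(col).strip().lower()
        if low in {"id", "entry", "accession", "gene", "identifier"}:
            rename[col] = "id"
        elif "sequence" in low or low == "seq":
            rename[col] = "sequence"
        elif "mature" in low and ("length" in low or "len" in low or "aa" in low):
            rename[col] = "mature_length"
        elif low in {"length", "len", "aa"}:
            rename.setdefault(col, "mature_length")
        elif "phylum" in low:
            rename[col] = "phylum"
        elif low == "class" or "class" in low:
            rename[col] = "class"
    df = df.rename(columns=rename)
    if "id" not in df.columns:
        raise ValueError(f"{path}: could not identify an id column "
                         f"among {list(df.columns)}")
    if "sequence" not in df.columns and "mature_length" not in df.columns:
        raise ValueError(f"{path}: need a sequence or mature-length column")
    if "sequence" not in df.columns:
        logger.info("%s ships mature lengths only; sequence operations "
                    "will be skipped", path.name)
    records = []
    for _, row in df.iterrows():
        rec = PrepilinRecord(
            id=str(row["id"]),
            sequence=str(row.get("sequence", "") or "").upper().replace("*", ""),
            phylum=str(row.get("phylum", "") or ""),
            klass=str(row.get("class", "") or ""),
        )
        if "mature_length" in df.columns and pd.notna(row.get("mature_length")):
            rec.mature_length = int(row["mature_length"])
        records.append(rec)
    return records
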