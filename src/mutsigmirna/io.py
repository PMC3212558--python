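"""Readers, writers and the run manifest.

All on-disk formats are plain text: FASTA for sequences, TSV for mutations,
genotype calls and result tables, BED for intervals and predicted sites,
JSON for run manifests.  VCF input is supported for genotype calls (GT and
per-sample DP).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import InputError
from .mutmodel import PointMutation
from .popgc import CALL_COLUMNS, SnpCallSet
from .seedscan import BindingSite, MatureMiRNA, UtrRecord

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs.

    The id is the first whitespace-separated header token; sequences are
    upper-cased.  ``alphabet='rna'`` maps T to U; ``'dna'`` rejects U.
    Duplicate ids and empty files are errors.
    """
    if alphabet not in ("dna", "rna"):
        raise InputError(f"unknown alphabet {alphabet!r}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise InputError(f"{path}: duplicate FASTA id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        if alphabet == "rna":
            seq = seq.replace("T", "U")
        elif "U" in seq:
            raise InputError(f"{path}: record {rid!r} contains U in DNA mode")
        records.append((rid, seq))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    return records


def load_utrs(path: str | Path) -> list[UtrRecord]:
    """Load 3'UTRs from FASTA, dropping records with ambiguity codes.

    Records containing characters outside A/C/G/T (e.g. N) are dropped with
    a logged count, per the scanner's strict alphabet.
    """
    out = []
    dropped = 0
    for rid, seq in read_fasta(path, "dna"):
        if set(seq) - set("ACGT"):
            dropped += 1
            continue
        out.append(UtrRecord(rid, seq))
    if dropped:
        logger.warning("%s: dropped %d UTR record(s) containing ambiguity codes", path, dropped)
    if not out:
        raise InputError(f"{path}: no usable UTR records")
    return out


def load_mirnas(path: str | Path) -> list[MatureMiRNA]:
    """Load mature miRNAs from FASTA (T silently converted to U)."""
    return [MatureMiRNA(rid, seq) for rid, seq in read_fasta(path, "rna")]


def write_fasta(path: str | Path, records) -> None:
    """Write UtrRecord/MatureMiRNA objects (or (id, seq) pairs) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rid, seq = rec
            elif isinstance(rec, UtrRecord):
                rid, seq = rec.gene_id, rec.sequence
            else:
                rid, seq = rec.id, rec.sequence
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_mutations(path: str | Path, utrs: list[UtrRecord]) -> list[PointMutation]:
    """Read a mutation TSV (gene_id, offset, ref, alt) validated against UTRs.

    Offsets are 0-based.  Each record's ref allele must agree with the UTR
    sequence; violations are reported with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ref": str, "alt": str})
    need = {"gene_id", "offset", "ref", "alt"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: mutation table needs columns {sorted(need)}")
    if df.empty:
        logger.warning("%s: header-only mutation file; no mutations loaded", path)
        return []
    by_id = {u.gene_id: u for u in utrs}
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            m = PointMutation(str(row.gene_id), int(row.offset), row.ref, row.alt)
        except InputError as exc:
            raise InputError(f"{path} line {line}: {exc}") from None
        if m.gene_id not in by_id:
            raise InputError(f"{path} line {line}: unknown gene {m.gene_id!r}")
        seq = by_id[m.gene_id].sequence
        if m.offset >= len(seq):
            raise InputError(f"{path} line {line}: offset {m.offset} beyond UTR length {len(seq)}")
        if seq[m.offset] != m.ref:
            raise InputError(
                f"{path} line {line}: ref mismatch at {m.gene_id}@{m.offset} "
                f"(file says {m.ref}, UTR has {seq[m.offset]})"
            )
        out.append(m)
    return out


def write_mutations(path: str | Path, muts: list[PointMutation]) -> None:
    pd.DataFrame(
        [(m.gene_id, m.offset, m.ref, m.alt) for m in muts],
        columns=["gene_id", "offset", "ref", "alt"],
    ).to_csv(path, sep="\t", index=False)


def genomic_to_utr(
    df: pd.DataFrame, annotations: pd.DataFrame
) -> list[tuple[str, int, str, str]]:
    """Map genomic mutations (chrom, pos 1-based, ref, alt) into UTR space.

    ``annotations`` is BED-like per gene: gene_id, chrom, start (0-based),
    end, strand.  Minus-strand genes get their offset flipped and alleles
    reverse-complemented, yielding the sense-strand UTR representation.
    """
    need = {"gene_id", "chrom", "start", "end", "strand"}
    if not need <= set(annotations.columns):
        raise InputError(f"UTR annotation needs columns {sorted(need)}")
    out = []
    for row in df.itertuples(index=False):
        pos0 = int(row.pos) - 1
        hit = annotations[
            (annotations["chrom"] == row.chrom)
            & (annotations["start"] <= pos0)
            & (pos0 < annotations["end"])
        ]
        if hit.empty:
            logger.warning("genomic mutation %s:%s outside all UTR annotations; skipped", row.chrom, row.pos)
            continue
        a = hit.iloc[0]
        if a["strand"] == "+":
            out.append((a["gene_id"], pos0 - int(a["start"]), row.ref, row.alt))
        else:
            out.append(
                (
                    a["gene_id"],
                    int(a["end"]) - 1 - pos0,
                    reverse_complement(row.ref),
                    reverse_complement(row.alt),
                )
            )
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame (0-based half-open intervals).

    The optional name column is surfaced as ``mirna_id`` for target files.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise InputError(f"{path} line {ln}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise InputError(f"{path} line {ln}: non-integer coordinates") from None
            if start >= end:
                raise InputError(f"{path} line {ln}: start >= end")
            rows.append(
                (
                    parts[0],
                    start,
                    end,
                    parts[3] if len(parts) > 3 else ".",
                    parts[4] if len(parts) > 4 else ".",
                    parts[5] if len(parts) > 5 else "+",
                )
            )
    if not rows:
        raise InputError(f"{path}: empty BED file")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    df["mirna_id"] = df["name"]
    return df


def write_sites(bed_path: str | Path, sites: list[BindingSite], tsv_path: str | Path | None = None) -> None:
    """Write predicted sites as BED6 in UTR space, plus a TSV with n_paired.

    BED chrom = gene_id, score = summed H-bonds, strand = '+' (miRNA:mRNA
    hybridisation is strand-specific; UTRs are sense-strand).
    """
    with open(bed_path, "w") as fh:
        for s in sites:
            fh.write(f"{s.gene_id}\t{s.offset}\t{s.offset + 7}\t{s.mirna_id}\t{s.score}\t+\n")
    if tsv_path is not None:
        pd.DataFrame(
            [(s.gene_id, s.offset, s.mirna_id, s.score, s.n_paired) for s in sites],
            columns=["gene_id", "offset", "mirna_id", "score", "n_paired"],
        ).to_csv(tsv_path, sep="\t", index=False)


def read_genotypes(path: str | Path, population: str | None = None) -> SnpCallSet:
    """Read genotype calls from a simple TSV or a VCF.

    TSV columns: chrom, pos (1-based), sample, allele1, allele2, dp.  VCF
    input uses per-sample GT and DP; a missing DP is treated as 0 (fails
    any dp_min >= 1) with a counted warning, and calls with missing alleles
    are skipped.
    """
    path = Path(path)
    name = population or path.stem
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path, name)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "allele1": str, "allele2": str})
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: genotype TSV missing columns {sorted(missing)}")
    return SnpCallSet(name, df[CALL_COLUMNS])


def _read_vcf(path: Path, population: str) -> SnpCallSet:
    import pysam

    rows = []
    n_missing_dp = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alleles = rec.alleles
            for sample, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or any(g is None for g in gt) or len(gt) != 2:
                    continue
                a1, a2 = alleles[gt[0]], alleles[gt[1]]
                if len(a1) != 1 or len(a2) != 1 or {a1, a2} - set("ACGT"):
                    continue  # indel or symbolic allele
                dp = call.get("DP")
                if dp is None:
                    n_missing_dp += 1
                    dp = 0
                rows.append((rec.chrom, rec.pos, sample, a1, a2, int(dp)))
    if n_missing_dp:
        logger.warning("%s: %d call(s) lacked DP; treated as depth 0", path, n_missing_dp)
    if not rows:
        raise InputError(f"{path}: no usable genotype calls")
    return SnpCallSet(population, pd.DataFrame(rows, columns=CALL_COLUMNS))


def write_genotypes(path: str | Path, calls: SnpCallSet) -> None:
    calls.calls.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list:
    """Read an external-program prediction TSV into ImportedPredictions.

    Columns: program, gene_id, mirna_id, threshold, bound{0,1} or sites,
    optional sequence{wt,mut}.  One object per distinct program.
    """
    from .bindshift import ImportedPredictions

    df = pd.read_csv(path, sep="\t")
    if "program" not in df.columns:
        raise InputError(f"{path}: prediction table needs a 'program' column")
    return [
        ImportedPredictions(str(prog), sub.drop(columns=["program"]).reset_index(drop=True))
        for prog, sub in df.groupby("program")
    ]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    parameters: dict
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    version: str = "0.1.0"
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def add_input(self, label: str, path: str | Path) -> None:
        self.input_digests[label] = file_digest(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")
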