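"""Readers, writers and coordinate conventions shared by all modules.

Interchange formats are deliberately plain: FASTA for sequences (via
Biopython), tab-separated tables for allele records and ratio series, a
minimal VCF-style table for variants and BED for interval output.  External
coordinates are 1-based inclusive (genome-browser style); internal spans are
0-based half-open, with lossless converters between the two.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .audit import Callset, OffTargetSite, Variant

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf_lite",
    "write_vcf_lite",
    "read_allele_table",
    "write_allele_table",
    "read_ratio_series",
    "write_ratio_series",
    "write_bed",
    "pos_to_zero_based",
    "zero_based_to_pos",
    "span_to_zero_based",
    "zero_based_to_span",
    "span_length",
    "provenance_header",
]

ALLELE_COLUMNS = ["cell_id", "allele_id", "a_um", "b_um", "rep_ose", "rep_myc", "signal_au"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: upper-cased sequence}.

    Duplicate record names are rejected; an empty file returns an empty
    mapping with a warning.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA record name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_vcf_lite(path: str | Path, caller_key: str = "caller") -> Callset:
    """Read a minimal VCF (or headered TSV) into a :class:`Callset`.

    Accepts either VCF layout (``#CHROM POS ID REF ALT [... INFO]``, caller
    taken from the ``caller=`` INFO key) or a plain TSV with ``chrom``,
    ``pos``, ``ref``, ``alt`` and optionally ``caller`` columns.
    Multi-allelic ALT fields are split into one variant per allele.
    Malformed rows raise with their line number.
    """
    path = Path(path)
    variants: list[Variant] = []
    header: list[str] | None = None
    vcf_style = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.lstrip("#").split("\t")
                vcf_style = True
                continue
            if line.startswith("#"):  # provenance or free comment
                continue
            if header is None:
                header = [c.lower() for c in line.split("\t")]
                if "chrom" not in header:
                    raise ValueError(
                        f"{path}:{lineno}: no #CHROM header and no 'chrom' column"
                    )
                continue
            fields = dict(zip(header, line.split("\t")))
            try:
                if vcf_style:
                    chrom, pos = fields["CHROM"], int(fields["POS"])
                    ref, alts = fields["REF"], fields["ALT"]
                    caller = ""
                    for item in fields.get("INFO", "").split(";"):
                        if item.startswith(caller_key + "="):
                            caller = item.split("=", 1)[1]
                else:
                    chrom, pos = fields["chrom"], int(fields["pos"])
                    ref, alts = fields["ref"], fields["alt"]
                    caller = fields.get(caller_key, "")
                for alt in alts.split(","):
                    callers = frozenset({caller}) if caller else frozenset()
                    variants.append(Variant(chrom, pos, ref.upper(), alt.upper(), callers))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed variant row ({exc})") from exc
    return Callset(variants)


def write_vcf_lite(callset: Callset, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, fmt="vcf-lite"))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tINFO\n")
        for v in callset:
            info = f"caller={','.join(sorted(v.callers))}" if v.callers else "."
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{info}\n")


def read_allele_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ALLELE_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise ValueError(f"allele table missing columns: {sorted(missing)}")
    if (frame["a_um"] < 0).any() or (frame["b_um"] < 0).any():
        raise ValueError("periphery distances must be >= 0")
    return frame


def write_allele_table(frame: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, fmt="allele-table"))
        frame.to_csv(fh, sep="\t", index=False)


def read_ratio_series(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    if not {"day", "ratio"} <= set(frame.columns):
        raise ValueError("ratio series needs 'day' and 'ratio' columns")
    if (frame["ratio"] <= 0).any():
        raise ValueError("ratios must be > 0")
    return frame


def write_ratio_series(frame: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, fmt="ratio-series"))
        frame.to_csv(fh, sep="\t", index=False)


def write_bed(sites: Iterable[OffTargetSite], path: str | Path, seed: int | None = None) -> None:
    """Write off-target sites as BED6 (score = protospacer mismatches)."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, fmt="bed"))
        for s in sites:
            name = f"mm{s.mismatches}" + ("" if s.pam_ok else ";noPAM")
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t{s.mismatches}\t{s.strand}\n")


# ---------------------------------------------------------------------------
# Coordinate conventions
# ---------------------------------------------------------------------------


def pos_to_zero_based(pos: int) -> tuple[int, int]:
    """1-based position -> 0-based half-open single-base span."""
    if pos < 1:
        raise ValueError("1-based positions start at 1")
    return pos - 1, pos


def zero_based_to_pos(start0: int, end0: int) -> int:
    if end0 - start0 != 1:
        raise ValueError("expected a single-base span")
    return start0 + 1


def span_to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive span -> 0-based half-open span (lossless)."""
    if start1 < 1 or end1 < start1:
        raise ValueError("invalid 1-based inclusive span")
    return start1 - 1, end1


def zero_based_to_span(start0: int, end0: int) -> tuple[int, int]:
    if start0 < 0 or end0 <= start0:
        raise ValueError("invalid 0-based half-open span")
    return start0 + 1, end0


def span_length(start1: int, end1: int) -> int:
    """Length in bp of a 1-based inclusive span."""
    s0, e0 = span_to_zero_based(start1, end1)
    return e0 - s0


def provenance_header(seed: int | None = None, fmt: str = "", config: dict | None = None) -> str:
    """Comment header recording version, seed and a config digest."""
    from . import __version__

    digest = ""
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
    parts = [f"genegate v{__version__}"]
    if fmt:
        parts.append(f"format={fmt}")
    if seed is not None:
        parts.append(f"seed={seed}")
    if digest:
        parts.append(f"config_sha={digest}")
    return "# " + " ".join(parts) + "\n"
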