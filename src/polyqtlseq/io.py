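"""Readers and writers: allele-count TSV dialect, VCF adapter, FASTA, run manifest.

The canonical interchange format is a tab-separated table with header
``chrom  pos  ref  alt  depth  alt_depth`` (1-based positions), one file per
sample.  VCF support is read-only and maps per-sample allele depths (the
standard ``AD`` format field) onto the same schema.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .snpindex import COUNT_COLUMNS, sort_by_position

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_vcf_counts",
    "read_fasta",
    "write_fasta",
    "write_manifest",
]

_VALID_BASES = frozenset("ACGT")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read and validate an allele-count TSV (CRLF tolerated).

    Malformed rows raise ValueError naming the 1-based file line number
    (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[COUNT_COLUMNS]
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        if row.pos < 1:
            raise ValueError(f"{path} line {line}: pos must be >= 1")
        if row.depth < 0 or row.alt_depth < 0 or row.alt_depth > row.depth:
            raise ValueError(
                f"{path} line {line}: require 0 <= alt_depth <= depth "
                f"(got depth={row.depth}, alt_depth={row.alt_depth})"
            )
        if row.ref not in _VALID_BASES or row.alt not in _VALID_BASES:
            raise ValueError(f"{path} line {line}: bases must be one of A/C/G/T")
        if row.ref == row.alt:
            raise ValueError(f"{path} line {line}: ref == alt")
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an allele-count TSV, sorted by natural chromosome order then position."""
    out = sort_by_position(df[COUNT_COLUMNS].copy())
    out.to_csv(path, sep="\t", index=False)


def read_vcf_counts(path: str | Path, samples: Iterable[str]) -> dict[str, pd.DataFrame]:
    """Extract per-sample allele counts from a VCF via the AD format field.

    Only biallelic-style SNP records are used (indels skipped, logged);
    multi-allelic sites keep the majority alternate per sample, an exact tie
    drops the site for that sample.  Depth is the sum of the AD entries.
    """
    from cyvcf2 import VCF

    samples = list(samples)
    vcf = VCF(str(path))
    idx = {}
    for s in samples:
        if s not in vcf.samples:
            raise ValueError(f"sample {s!r} not in VCF ({vcf.samples})")
        idx[s] = vcf.samples.index(s)
    rows: dict[str, list] = {s: [] for s in samples}
    for v in vcf:
        if not v.is_snp:
            logger.info("skipping non-SNP record at %s:%d", v.CHROM, v.POS)
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"missing AD field at {v.CHROM}:{v.POS} (samples {samples})")
        alts = [a for a in v.ALT if len(a) == 1 and a in _VALID_BASES]
        if not alts:
            continue
        for s in samples:
            counts = [int(c) for c in ad[idx[s]]]
            counts = [max(c, 0) for c in counts]  # missing encoded negative
            ref_c = counts[0]
            alt_counts = counts[1 : 1 + len(v.ALT)]
            pairs = [
                (alt_counts[k], a)
                for k, a in enumerate(v.ALT)
                if len(a) == 1 and a in _VALID_BASES and k < len(alt_counts)
            ]
            if not pairs:
                continue
            top = max(c for c, _ in pairs)
            winners = [a for c, a in pairs if c == top]
            if len(winners) > 1 and top > 0:
                logger.info("%s: alternate tie at %s:%d, site dropped", s, v.CHROM, v.POS)
                continue
            rows[s].append(
                (v.CHROM, v.POS, v.REF, winners[0], ref_c + sum(c for c, _ in pairs), top)
            )
    return {
        s: pd.DataFrame(rows[s], columns=COUNT_COLUMNS)
        for s in samples
    }


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_manifest(path: str | Path, stage: str, params: Mapping, seeds: Mapping) -> None:
    """JSON run manifest: package version, stage, parameters and seeds."""
    from . import __version__

    manifest = {
        "package": "polyqtlseq",
        "version": __version__,
        "stage": stage,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "seeds": dict(seeds),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if hasattr(v, "__dict__") and not isinstance(v, type):
        try:
            import dataclasses

            if dataclasses.is_dataclass(v):
                return {k: _jsonable(x) for k, x in dataclasses.asdict(v).items()}
        except Exception:
            pass
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
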