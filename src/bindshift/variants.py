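"""Variant loading, flank extraction and the per-variant ranking pipeline.

Single-nucleotide variants are read from VCF or a simple TSV, a window of
2 * flank + 1 bases (61 bp by default) centred on each variant is pulled
from an indexed genome FASTA, and every variant is pushed through the
scan -> filter -> integrate pipeline to yield a ranked TF prediction.

Coordinates are 1-based in all user-facing records (VCF convention) and
0-based half-open internally. When the genome base disagrees with the
stated reference allele the variant is flagged and the genome base is
trusted; windows that would overhang a chromosome end are truncated with
a warning rather than dropped.
"""

from __future__ import annotations

import logging
import zlib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .affinity import DEFAULT_MU_GRID, DeltaTable, scan_variant
from .integration import RankedPrediction, build_integration_matrix, mutation_score, pca_integrate
from .motifs import EnergyMatrix, Pwm, pwm_to_energy

__all__ = [
    "Variant",
    "PipelineConfig",
    "VariantResult",
    "PipelineResult",
    "load_variants",
    "write_variants_tsv",
    "extract_sequences",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Variant:
    """One SNV with (optionally) its extracted reference/mutated flank windows."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    id: str = ""
    ref_seq: str = ""
    mut_seq: str = ""
    window_start: int = 0  # 1-based start of the extracted window
    ref_mismatch: bool = False
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"variant {self.id or self.key()!r}: alleles must be single bases")
        if self.pos < 1:
            raise ValueError(f"variant {self.id!r}: position must be 1-based and >= 1")

    def key(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref_allele}_{self.alt_allele}"


def _variant_id(chrom: str, pos: int, ref: str, alt: str, vid: Optional[str]) -> str:
    return vid if vid not in (None, "", ".") else f"{chrom}_{pos}_{ref}_{alt}"


def _load_vcf(path: Path) -> tuple[list[Variant], int]:
    import pysam

    out: list[Variant] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            ref = rec.ref or ""
            for alt in rec.alts or ():
                if len(ref) != 1 or alt is None or len(alt) != 1 or not alt.isalpha():
                    skipped += 1
                    continue
                out.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=ref.upper(),
                        alt_allele=alt.upper(),
                        id=_variant_id(rec.chrom, rec.pos, ref, alt, rec.id),
                    )
                )
    return out, skipped


def _load_tsv(path: Path) -> tuple[list[Variant], int]:
    out: list[Variant] = []
    skipped = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected columns chrom, pos, ref, alt[, id]")
            chrom, pos_s, ref, alt = fields[:4]
            vid = fields[4] if len(fields) > 4 else None
            try:
                pos = int(pos_s)
            except ValueError:
                if lineno == 1 or (not out and skipped == 0):
                    continue  # header line
                raise ValueError(f"{path}:{lineno}: position {pos_s!r} is not an integer") from None
            for one_alt in alt.split(","):
                if len(ref) != 1 or len(one_alt) != 1:
                    skipped += 1
                    continue
                out.append(
                    Variant(
                        chrom=chrom,
                        pos=pos,
                        ref_allele=ref.upper(),
                        alt_allele=one_alt.upper(),
                        id=_variant_id(chrom, pos, ref, one_alt, vid),
                    )
                )
    return out, skipped


def load_variants(path, format: Optional[str] = None) -> list[Variant]:
    """Load SNVs from VCF (plain or bgzipped) or TSV (chrom, pos, ref, alt[, id]).

    Multi-allelic records expand to one variant per ALT; records that are
    not single-base substitutions are skipped and counted in the log.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"variant file does not exist: {p}")
    if format is None:
        format = "vcf" if p.name.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        variants, skipped = _load_vcf(p)
    elif format == "tsv":
        variants, skipped = _load_tsv(p)
    else:
        raise ValueError(f"unknown variant format {format!r}")
    if skipped:
        log.info("skipped %d non-SNV record(s) in %s", skipped, p)
    return variants


def write_variants_tsv(variants: Sequence[Variant], path) -> None:
    """Write variants as a TSV that :func:`load_variants` reads back."""
    with open(path, "w") as out:
        out.write("#chrom\tpos\tref\talt\tid\n")
        for v in variants:
            out.write(f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t{v.id}\n")


def extract_sequences(variant: Variant, genome, flank: int = 30) -> Variant:
    """Fill ref_seq/mut_seq with the window of 2*flank+1 bases around the variant.

    ``genome`` is a pyfaidx.Fasta (or a path to an indexed FASTA). The
    mutated window is the reference window with the centre base replaced by
    the ALT allele. Near a chromosome end the window is truncated (flagged);
    a reference-allele mismatch against the genome is flagged and the genome
    base wins.
    """
    import pyfaidx

    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    fasta = pyfaidx.Fasta(str(genome)) if isinstance(genome, (str, Path)) else genome
    if variant.chrom not in fasta:
        raise KeyError(f"chromosome {variant.chrom!r} not found in the genome FASTA")
    chrom_len = len(fasta[variant.chrom])
    if variant.pos > chrom_len:
        raise ValueError(
            f"variant {variant.id!r}: position {variant.pos} beyond chromosome "
            f"{variant.chrom!r} (length {chrom_len})"
        )
    start = max(variant.pos - 1 - flank, 0)  # 0-based half-open
    end = min(variant.pos + flank, chrom_len)
    ref_seq = str(fasta[variant.chrom][start:end]).upper()
    centre = variant.pos - 1 - start
    truncated = len(ref_seq) != 2 * flank + 1
    if truncated:
        log.warning(
            "variant %s: window truncated to [%d, %d) at the %s boundary",
            variant.id, start + 1, end, variant.chrom,
        )
    genome_base = ref_seq[centre]
    mismatch = genome_base != variant.ref_allele.upper()
    if mismatch:
        log.warning(
            "variant %s: genome base %s at %s:%d does not match stated reference allele %s; "
            "using the genome base",
            variant.id, genome_base, variant.chrom, variant.pos, variant.ref_allele,
        )
    mut_seq = ref_seq[:centre] + variant.alt_allele.upper() + ref_seq[centre + 1 :]
    return replace(
        variant,
        ref_allele=genome_base,
        ref_seq=ref_seq,
        mut_seq=mut_seq,
        window_start=start + 1,
        ref_mismatch=mismatch,
        truncated=truncated,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the per-variant ranking pipeline."""

    mu_grid: tuple = DEFAULT_MU_GRID
    R: int = 100  # shuffles per sequence
    seed: int = 0
    alpha: float = 0.05  # direct-binding filter level
    flank: int = 30  # 61 bp windows
    w: float = 1.0  # dbA weight coefficient
    workers: int = 1
    pseudocount: float = 0.01
    min_direct: int = 1
    model: str = "fermi_dirac"


@dataclass(frozen=True)
class VariantResult:
    variant: Variant
    table: Optional[DeltaTable] = None
    prediction: Optional[RankedPrediction] = None
    score: float = 0.0
    error: Optional[str] = None


@dataclass(frozen=True)
class PipelineResult:
    results: dict  # variant id -> VariantResult, input order preserved
    summary: pd.DataFrame

    def write(self, outdir) -> None:
        """Write per-variant ranking and delta TSVs plus the summary table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for vid, res in self.results.items():
            if res.error is not None:
                continue
            safe = vid.replace("/", "_")
            res.prediction.to_frame().to_csv(outdir / f"{safe}.ranking.tsv", sep="\t", index=False)
            res.table.to_tsv(outdir / f"{safe}.deltas.tsv")
        self.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)


def variant_seed(global_seed: int, variant_id: str) -> int:
    """Per-variant shuffle seed: stable in the id, independent of input order."""
    return (int(global_seed) + zlib.crc32(variant_id.encode())) % (2**31)


def _process_one(args) -> VariantResult:
    variant, energies, config = args
    try:
        table = scan_variant(
            energies,
            variant.ref_seq,
            variant.mut_seq,
            mu_grid=config.mu_grid,
            R=config.R,
            seed=variant_seed(config.seed, variant.id),
            alpha=config.alpha,
            w=config.w,
            model=config.model,
            variant_id=variant.id,
        )
        M = build_integration_matrix(table, min_direct=config.min_direct)
        prediction = pca_integrate(M, variant_id=variant.id)
        score = mutation_score(prediction, table)
        return VariantResult(variant=variant, table=table, prediction=prediction, score=score)
    except Exception as exc:  # per-variant failures must not kill the batch
        log.error("variant %s failed: %s", variant.id, exc)
        return VariantResult(variant=variant, error=str(exc))


def run_pipeline(
    variants: Sequence[Variant],
    pwms: Sequence[Union[Pwm, EnergyMatrix]],
    genome=None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Rank TF binding changes for a batch of variants.

    Each variant gets its own shuffle seed derived from the global seed and
    its id, so results do not depend on input order or on ``workers``.
    Per-variant failures are recorded in the summary and processing
    continues. ``pwms`` may hold PWMs (converted with ``config.pseudocount``)
    or ready-made energy matrices.
    """
    if not pwms:
        raise ValueError("motif collection is empty")
    energies = [
        p if isinstance(p, EnergyMatrix) else pwm_to_energy(p, config.pseudocount) for p in pwms
    ]
    filled = []
    for v in variants:
        if not v.ref_seq:
            if genome is None:
                raise ValueError(f"variant {v.id!r} has no sequences and no genome was given")
            v = extract_sequences(v, genome, flank=config.flank)
        filled.append(v)

    tasks = [(v, energies, config) for v in filled]
    if config.workers > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(_process_one, tasks))
    else:
        results = [_process_one(t) for t in tasks]

    by_id = {r.variant.id: r for r in results}
    rows = []
    for r in results:
        pred = r.prediction
        rows.append(
            {
                "variant_id": r.variant.id,
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "n_direct": len(pred.scores) if pred is not None else 0,
                "mutation_score": r.score,
                "top_positive_tf": pred.tf_positive[0] if pred and pred.tf_positive else "",
                "top_negative_tf": pred.tf_negative[0] if pred and pred.tf_negative else "",
                "ref_mismatch": r.variant.ref_mismatch,
                "error": r.error or "",
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "n_direct", "mutation_score",
            "top_positive_tf", "top_negative_tf", "ref_mismatch", "error",
        ],
    )
    return PipelineResult(results=by_id, summary=summary)
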