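"""Read, harmonize and filter SNP genotype data for a genomic region.

Input is VCF 4.x (GT required, GP optional).  Only biallelic SNPs (or
explicit biallelic indels) are kept; multiallelic records are skipped and
counted, not split, because the downstream classifier indexes genotypes by
alt-allele count in {0,1,2}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    EmptyRegionError,
    GenotypeMatrix,
    GenotypeProbMatrix,
    NoOverlapError,
    VariantSite,
)

if TYPE_CHECKING:  # pragma: no cover
    from .reference import InversionReference

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: GP triples whose sum deviates from 1 by more than this are treated as
#: missing; smaller deviations (dosage-format rounding) are renormalized.
GP_SUM_TOL = 1e-3


@dataclass
class HarmonizeReport:
    """Site accounting from :func:`harmonize_to_reference`."""

    n_matched: int = 0
    n_flipped: int = 0
    n_strand_ambiguous_dropped: int = 0
    n_irreconcilable_dropped: int = 0
    n_absent_from_query: int = 0


def _is_strand_ambiguous(ref: str, alt: str) -> bool:
    return {ref, alt} in ({"A", "T"}, {"C", "G"})


def read_genotypes(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    want_probs: bool = False,
) -> GenotypeMatrix | tuple[GenotypeMatrix, GenotypeProbMatrix]:
    """Read biallelic SNP genotypes from a VCF.

    Parameters
    ----------
    path : str or Path
        VCF file (plain or bgzipped).
    region : (chrom, start, end), optional
        1-based inclusive coordinates.  ``None`` reads the whole file.
    want_probs : bool
        Also return a :class:`GenotypeProbMatrix` built from the GP FORMAT
        field, falling back to one-hot triples from GT where GP is absent.

    Returns
    -------
    GenotypeMatrix, or (GenotypeMatrix, GenotypeProbMatrix) if
    ``want_probs``.

    Raises
    ------
    OSError
        Unreadable file.
    EmptyRegionError
        No biallelic SNP records in the region.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"VCF not found: {path}")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)

    sites: list[VariantSite] = []
    code_cols: list[np.ndarray] = []
    prob_cols: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if region is not None:
            chrom, start, end = region
            if rec.CHROM != chrom or not (start <= rec.POS <= end):
                continue
        if len(rec.ALT) != 1 or rec.ALT[0] in (".", "") or "<" in rec.ALT[0]:
            n_skipped += 1
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        sites.append(VariantSite(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        # gts012=True: gt_types is 0/1/2 alt copies, 3 = unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        code_cols.append(gt)
        if want_probs:
            gp = None
            try:
                gp = rec.format("GP")
            except KeyError:
                gp = None
            if gp is not None:
                gp = np.asarray(gp, dtype=float)
                prob_cols.append(_clean_gp(gp))
            else:
                prob_cols.append(_onehot_col(gt))
    if n_skipped:
        logger.info(
            "%s: skipped %d multiallelic/non-SNP records", path.name, n_skipped
        )
    if not sites:
        where = f"region {region}" if region else "file"
        raise EmptyRegionError(f"no biallelic SNPs in {where} of {path}")

    codes = np.stack(code_cols, axis=1)
    gm = GenotypeMatrix(samples, sites, codes)
    if not want_probs:
        return gm
    probs = np.stack(prob_cols, axis=1)
    return gm, GenotypeProbMatrix(samples, list(sites), probs)


def _clean_gp(gp: np.ndarray) -> np.ndarray:
    """Renormalize GP triples; off-by-more-than-tol or negative -> missing."""
    gp = gp.astype(float).copy()
    gp[gp < 0] = np.nan  # cyvcf2 encodes missing as negative sentinels
    sums = gp.sum(axis=1)
    bad = ~np.isfinite(sums) | (np.abs(sums - 1.0) > GP_SUM_TOL)
    gp[bad] = np.nan
    ok = ~bad
    gp[ok] /= sums[ok, None]
    return gp


def _onehot_col(gt: np.ndarray) -> np.ndarray:
    col = np.full((gt.shape[0], 3), np.nan)
    called = gt != MISSING
    col[called] = 0.0
    col[called, gt[called]] = 1.0
    return col


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write hard genotype codes to an uncompressed VCF 4.2 file.

    Round-trips exactly through :func:`read_genotypes`.
    """
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in gm.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, site in enumerate(gm.sites):
            gts = "\t".join(gt_map[int(c)] for c in gm.codes[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.id}\t{site.ref_allele}\t"
                f"{site.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read experimental inversion-genotype labels from a 2-column TSV.

    Expected header: ``sample\tinv_genotype``; labels in {NN, NI, II}
    (or {N, I} for hemizygous males).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "inv_genotype"]:
        raise ValueError(
            f"label table must have columns 'sample' and 'inv_genotype', "
            f"got {list(df.columns)}"
        )
    if df["sample"].duplicated().any():
        dups = df["sample"][df["sample"].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in label table: {dups}")
    allowed = {"NN", "NI", "II", "N", "I"}
    bad = set(df["inv_genotype"]) - allowed
    if bad:
        raise ValueError(f"invalid inversion-genotype labels: {sorted(bad)}")
    return dict(zip(df["sample"], df["inv_genotype"]))


def write_label_table(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(labels), "inv_genotype": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def harmonize_to_reference(
    gm: GenotypeMatrix,
    ref: "InversionReference",
    return_report: bool = False,
) -> GenotypeMatrix | tuple[GenotypeMatrix, HarmonizeReport]:
    """Restrict and allele-align a query matrix to a reference panel.

    Sites are matched by (chrom, pos), falling back to id.  Query sites
    whose ref/alt are swapped relative to the panel are flipped
    (code x -> 2-x).  Strand-ambiguous sites (A/T, C/G) that cannot be
    matched unambiguously, and sites with irreconcilable alleles, are
    dropped and counted.  Idempotent: a harmonized matrix passes through
    unchanged.

    Raises
    ------
    NoOverlapError
        If no query site can be aligned to the panel.
    """
    by_key = {s.key: j for j, s in enumerate(gm.sites)}
    by_id = {s.id: j for j, s in enumerate(gm.sites)}

    rep = HarmonizeReport()
    keep_idx: list[int] = []
    out_codes: list[np.ndarray] = []
    out_sites: list[VariantSite] = []
    for rsite in ref.sites:
        j = by_key.get(rsite.key, by_id.get(rsite.id))
        if j is None:
            rep.n_absent_from_query += 1
            continue
        q = gm.sites[j]
        col = gm.codes[:, j].copy()
        if (q.ref_allele, q.alt_allele) == (rsite.ref_allele, rsite.alt_allele):
            rep.n_matched += 1
        elif (q.alt_allele, q.ref_allele) == (rsite.ref_allele, rsite.alt_allele):
            if _is_strand_ambiguous(q.ref_allele, q.alt_allele):
                # an A/T or C/G swap is indistinguishable from a strand flip
                rep.n_strand_ambiguous_dropped += 1
                continue
            called = col != MISSING
            col[called] = 2 - col[called]
            rep.n_flipped += 1
        else:
            qc = {_COMPLEMENT.get(q.ref_allele), _COMPLEMENT.get(q.alt_allele)}
            rc = {rsite.ref_allele, rsite.alt_allele}
            if qc == rc and not _is_strand_ambiguous(q.ref_allele, q.alt_allele):
                # opposite-strand report of the same alleles
                if _COMPLEMENT.get(q.ref_allele) == rsite.ref_allele:
                    rep.n_matched += 1
                else:
                    called = col != MISSING
                    col[called] = 2 - col[called]
                    rep.n_flipped += 1
            else:
                rep.n_irreconcilable_dropped += 1
                continue
        keep_idx.append(j)
        out_codes.append(col)
        out_sites.append(rsite)

    if rep.n_strand_ambiguous_dropped or rep.n_irreconcilable_dropped:
        logger.info(
            "harmonize: %d matched, %d flipped, %d strand-ambiguous dropped, "
            "%d irreconcilable dropped",
            rep.n_matched,
            rep.n_flipped,
            rep.n_strand_ambiguous_dropped,
            rep.n_irreconcilable_dropped,
        )
    if not out_sites:
        raise NoOverlapError(
            f"no query sites overlap reference panel {ref.inversion_id!r}"
        )
    out = GenotypeMatrix(
        list(gm.samples), out_sites, np.stack(out_codes, axis=1)
    )
    return (out, rep) if return_report else out


def filter_call_rate(gm: GenotypeMatrix, min_rate: float = 0.9) -> GenotypeMatrix:
    """Drop sites whose call rate across samples is strictly below min_rate.

    The default 0.9 matches the standard pre-scoring SNP quality filter;
    a site with call rate exactly min_rate is retained.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError(f"min_rate must be in [0,1], got {min_rate}")
    keep = np.nonzero(gm.call_rates() >= min_rate)[0]
    if len(keep) < gm.n_sites:
        logger.info(
            "call-rate filter: removed %d of %d sites",
            gm.n_sites - len(keep),
            gm.n_sites,
        )
    return gm.take_sites(keep)
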