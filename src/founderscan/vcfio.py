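"""Reading and writing cohorts as VCF v4.2 + phenotype TSV.

Records are biallelic with FORMAT GT:GQ:DP:AD; INFO carries the
functional class (``CLASS``), the high-confidence LoF flag (``LOF_HC``)
and per-population alternate-allele frequencies (``AF_POP1`` = founder,
``AF_POP2`` = outbred). Writing emits the fixed record layout directly
(a vectorized text path -- cohort matrices run to tens of millions of
genotypes, far past what a per-sample record API sustains); reading goes
through cyvcf2, and round-tripping a cohort reproduces its dosage matrix
exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simdata import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = ["write_cohort_vcf", "read_cohort_vcf", "write_phenotypes", "read_phenotypes", "emit_cohort"]


def _header_lines(samples) -> list[str]:
    return [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1,length=249250621>",
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Functional class">',
        '##INFO=<ID=LOF_HC,Number=0,Type=Flag,Description="High-confidence loss-of-function">',
        '##INFO=<ID=AF_POP1,Number=1,Type=Float,Description="Alternate allele frequency, founder population">',
        '##INFO=<ID=AF_POP2,Number=1,Type=Float,Description="Alternate allele frequency, outbred population">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]


def write_cohort_vcf(cohort: SyntheticCohort, path, depth: int = 30, gq: int = 99) -> Path:
    """Write a cohort to an uncompressed VCF v4.2 file.

    Synthesized FORMAT fields are internally consistent with the genotype:
    AD splits ``depth`` reads between the alleles (all-ref, half/half, or
    all-alt), so downstream QC sees clean calls unless the caller perturbs
    them.
    """
    path = Path(path)
    half = depth // 2
    # one fixed sample-field string per dosage value; index 3 = missing
    field_by_dosage = np.array(
        [
            f"0/0:{gq}:{depth}:{depth},0",
            f"0/1:{gq}:{depth}:{depth - half},{half}",
            f"1/1:{gq}:{depth}:0,{depth}",
            f"./.:{gq}:{depth}:.,.",
        ]
    )
    codes = np.where(cohort.dosages == SyntheticCohort.MISSING, 3, cohort.dosages)
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(_header_lines(list(cohort.samples["sample_id"]))) + "\n")
            for j, v in enumerate(cohort.variants.itertuples(index=False)):
                af1 = float(getattr(v, "af_founder", getattr(v, "q_founder", 0.0)) or 0.0)
                af2 = float(getattr(v, "af_outbred", getattr(v, "q_outbred", 0.0)) or 0.0)
                info = f"CLASS={v.var_class};AF_POP1={af1:.6g};AF_POP2={af2:.6g}"
                if bool(v.lof_hc):
                    info += ";LOF_HC"
                fixed = f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT:GQ:DP:AD\t"
                fh.write(fixed + "\t".join(field_by_dosage[codes[:, j]].tolist()) + "\n")
    except OSError as exc:
        raise OSError(f"failed to write VCF to {path}: {exc}") from exc
    return path


def read_cohort_vcf(path, population: str = "cohort") -> SyntheticCohort:
    """Read a conforming VCF back into a SyntheticCohort (no phenotypes)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such VCF: {path}")
    vcf = VCF(str(path), gts012=True)
    samples = pd.DataFrame(
        {"sample_id": vcf.samples, "sex": "unknown", "age": np.nan, "population": population}
    )
    rows, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping non-biallelic record %s:%s", rec.CHROM, rec.POS)
            continue
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "var_class": rec.INFO.get("CLASS", "unknown"),
                "lof_hc": bool(rec.INFO.get("LOF_HC", False)),
                "af_founder": rec.INFO.get("AF_POP1"),
                "af_outbred": rec.INFO.get("AF_POP2"),
            }
        )
        # gts012: 0/1/2 dosage, 3 = missing
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = SyntheticCohort.MISSING
        cols.append(g)
    vcf.close()
    dosages = np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    return SyntheticCohort(
        population=population, samples=samples, dosages=dosages, variants=pd.DataFrame(rows)
    )


def write_phenotypes(pheno: pd.DataFrame, path) -> Path:
    path = Path(path)
    pheno.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def emit_cohort(cohort: SyntheticCohort, out_dir, prefix: str | None = None) -> dict[str, Path]:
    """Write a cohort's VCF and (if present) phenotype TSV into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or cohort.population
    paths = {"vcf": write_cohort_vcf(cohort, out_dir / f"{prefix}.vcf")}
    if cohort.phenotypes is not None:
        paths["phenotypes"] = write_phenotypes(cohort.phenotypes, out_dir / f"{prefix}.pheno.tsv")
    return paths
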