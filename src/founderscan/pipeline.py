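"""End-to-end orchestration: simulate -> QC/select -> SFS/structure -> associate -> meta.

Every stage reads and writes self-describing TSV/JSON artifacts so a
downstream stage can be re-run from saved upstream outputs, and the whole
run is a deterministic function of (config, master seed). The packaged
default experiment simulates a founder and an outbred cohort, selects
founder-enriched LoF variants, compares the two site-frequency spectra,
screens for homozygote deficits, scans selected variants against the
simulated traits in a discovery/replication split, and combines the
splits by fixed-effects meta-analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, lofselect, metastats, popstruct, sfs, vcfio
from ._rng import stage_rng
from .popstruct import GenotypeCounts
from .simdata import EffectSpec, SimConfig, SyntheticCohort, VariantClassSpec, simulate_cohorts, simulate_phenotypes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    effects: tuple[EffectSpec, ...] = ()
    screen_p: float = 2e-4
    alpha: float = 0.05
    freq_window: tuple[float, float] = (0.005, 0.05)
    min_fold: float = 2.0
    concordance_threshold: float = 1e-5
    min_expected_hom: float = 3.0
    deficit_p: float = 0.05
    discovery_fraction: float = 0.67
    seed: int = 0
    out_dir: str = "founderscan_out"

    def __post_init__(self):
        for name in ("screen_p", "alpha", "concordance_threshold", "deficit_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if not 0 < self.discovery_fraction < 1:
            raise ValueError("discovery_fraction must lie in (0,1)")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file with per-stage blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {})
    class_specs = sim_raw.pop("class_specs", None)
    if class_specs is not None:
        sim_raw["class_specs"] = tuple(
            VariantClassSpec(
                label=c["label"],
                s=c.get("s", 0.0),
                h=c.get("h", 0.5),
                q0=tuple(c["q0"]) if isinstance(c.get("q0"), list) else c.get("q0", 0.01),
                q0_shape=c.get("q0_shape", "log"),
            )
            for c in class_specs
        )
    if "sample_sizes" in sim_raw:
        sim_raw["sample_sizes"] = dict(sim_raw["sample_sizes"])
    effects = tuple(EffectSpec(**e) for e in raw.pop("effects", []))
    if "freq_window" in raw:
        raw["freq_window"] = tuple(raw["freq_window"])
    return RunConfig(sim=SimConfig(**sim_raw), effects=effects, **raw)


def _json_dump(obj, path: Path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def _genotype_counts(cohort: SyntheticCohort) -> list[GenotypeCounts]:
    return [GenotypeCounts(*cohort.genotype_counts(j)) for j in range(cohort.n_variants)]


def run_pipeline(config: RunConfig, out_dir=None, seed: int | None = None) -> dict:
    """Execute the full analysis; returns the run-summary dict.

    Stages run in a fixed order and each failure is re-raised with a
    stage tag; artifacts written before the failure are retained.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = config.seed if seed is None else seed
    sim_cfg = config.sim.with_(seed=master_seed)
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": master_seed, "stages": {}}

    stage = "simulate"
    try:
        cohorts = simulate_cohorts(sim_cfg)
        founder, outbred = cohorts["founder"], cohorts["outbred"]
        effects = list(config.effects)
        if not effects:
            # default experiment: one LoF variant lowers a biomarker which drives disease
            lof_ids = founder.variants.loc[founder.variants["lof_hc"], "variant_id"]
            target = _pick_target_variant(founder, lof_ids)
            if target is not None:
                effects = [EffectSpec(variant=target, trait="biomarker", beta=-0.6, trait_loghr=0.3)]
        for pop, cohort in cohorts.items():
            simulate_phenotypes(cohort, effects, rng=stage_rng(master_seed, f"phenotypes:{pop}"))
            vcfio.emit_cohort(cohort, out)
        summary["stages"][stage] = {
            "n_samples": {p: c.n_samples for p, c in cohorts.items()},
            "n_variants": founder.n_variants,
            "effects": [dataclasses.asdict(e) for e in effects],
        }
        logger.info("simulate: %s samples, %d variants", summary["stages"][stage]["n_samples"], founder.n_variants)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "sfs"
    try:
        counts = sfs.cohort_variant_counts(cohorts)
        table = sfs.build_sfs(counts)
        table.to_frame().to_csv(out / "sfs.tsv", sep="\t", index=False)
        seg_f = sum(table.segregating("founder", c) for c in counts["var_class"].unique())
        seg_o = sum(table.segregating("outbred", c) for c in counts["var_class"].unique())
        lowfreq = _window_counts(counts, config.freq_window)
        enrich_p = sfs.class_enrichment_test(
            lowfreq["lof_founder"], lowfreq["syn_founder"], lowfreq["lof_outbred"], lowfreq["syn_outbred"]
        )
        burdens = {p: sfs.per_individual_burden(c) for p, c in cohorts.items()}
        pd.concat(
            [b.table.assign(population=p) for p, b in burdens.items()]
        ).to_csv(out / "burden.tsv", sep="\t", index=False)
        summary["stages"][stage] = {
            "segregating": {"founder": seg_f, "outbred": seg_o},
            "excess_binomial_p": sfs.excess_binomial_test(seg_f, seg_o) if seg_f + seg_o else None,
            "low_freq_window": lowfreq,
            "class_enrichment_p": enrich_p,
            "singletons_per_individual": {
                p: b.table.loc[b.table["bin"] == sfs.SINGLETON, "mean_sites"].sum() for p, b in burdens.items()
            },
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "popstruct"
    try:
        gcounts = [c for c in _genotype_counts(founder) if 0 < c.allele_count < 2 * c.n_total]
        try:
            fst = dataclasses.asdict(popstruct.estimate_fst(gcounts))
        except ValueError as exc:
            logger.warning("substructure estimate unavailable: %s", exc)
            fst = None
        try:
            fold = popstruct.fold_excess_homozygotes(gcounts)
        except ValueError as exc:
            logger.warning("fold-excess unavailable: %s", exc)
            fold = None
        flags = popstruct.homozygote_deficit_screen(
            {v: [c] for v, c in zip(founder.variants["variant_id"], _genotype_counts(founder))},
            min_expected=config.min_expected_hom,
            p_threshold=config.deficit_p,
        )
        popstruct.screen_report(flags).to_csv(out / "deficit_screen.tsv", sep="\t", index=False)
        summary["stages"][stage] = {
            "fst": fst,
            "fold_excess_homozygotes": fold,
            "n_deficit_flags": int(sum(f.flagged for f in flags)),
        }
        _json_dump(summary["stages"][stage], out / "popstruct.json")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "select"
    try:
        decisions = []
        af_f = founder.allele_freqs()
        af_o = outbred.allele_freqs()
        rng = stage_rng(master_seed, "concordance-split")
        for j, v in enumerate(founder.variants.itertuples(index=False)):
            if not v.lof_hc:
                continue
            conc = _reference_concordance(outbred, j, rng, config.concordance_threshold)
            decisions.append(
                lofselect.select_enriched(
                    v.variant_id, float(af_f[j]), float(af_o[j]),
                    confidence="high", concordance=conc,
                    freq_window=config.freq_window, min_fold=config.min_fold,
                )
            )
        sel = pd.DataFrame([dataclasses.asdict(d) for d in decisions])
        sel.to_csv(out / "selection.tsv", sep="\t", index=False)
        accepted = [d for d in decisions if d.accepted]
        summary["stages"][stage] = {
            "n_lof_considered": len(decisions),
            "n_accepted": len(accepted),
            "n_fold_gt2": sum(1 for d in accepted if d.fold_category == ">2"),
            "n_fold_gt10": sum(1 for d in accepted if d.fold_category == ">10"),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "assoc"
    try:
        results_disc, results_rep, traits = _association_scan(founder, accepted, config, master_seed)
        all_results = results_disc + results_rep
        pd.DataFrame(
            [dataclasses.asdict(r) | {"split": s} for rs, s in ((results_disc, "discovery"), (results_rep, "replication")) for r in rs]
        ).to_csv(out / "assoc.tsv", sep="\t", index=False)
        screen = assoc.screen_all(
            results_disc, n_variants=max(len(accepted), 1), n_traits=max(len(traits), 1),
            screen_p=config.screen_p, alpha=config.alpha,
        )
        _json_dump(screen, out / "screen.json")
        summary["stages"][stage] = {
            "n_variants_tested": len(accepted),
            "n_traits": len(traits),
            "n_screen_hits": screen["n_hits"],
            "expected_chance_hits": screen["expected_chance_hits"],
            "bonferroni_threshold": screen["bonferroni_threshold"],
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "meta"
    try:
        meta_rows = []
        rep_by_key = {(r.variant_id, r.trait): r for r in results_rep}
        for r in results_disc:
            rep = rep_by_key.get((r.variant_id, r.trait))
            if rep is None:
                continue
            m = metastats.ivw_meta([(r.effect, r.se), (rep.effect, rep.se)], ns=[r.n, rep.n])
            meta_rows.append(
                {
                    "variant_id": r.variant_id, "trait": r.trait,
                    "beta_disc": r.effect, "se_disc": r.se, "p_disc": r.p,
                    "beta_rep": rep.effect, "se_rep": rep.se, "p_rep": rep.p,
                    "beta_comb": m.effect, "se_comb": m.se, "p_comb": m.p,
                    "fisher_p": metastats.fisher_combined([r.p, rep.p]),
                }
            )
        pd.DataFrame(meta_rows).to_csv(out / "meta.tsv", sep="\t", index=False)
        summary["stages"][stage] = {"n_meta_rows": len(meta_rows)}
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    _json_dump(summary, out / "run_summary.json")
    return summary


def _pick_target_variant(cohort: SyntheticCohort, candidate_ids) -> str | None:
    """Deterministically pick a LoF variant with frequency nearest 2%."""
    af = cohort.allele_freqs()
    idx = {v: j for j, v in enumerate(cohort.variants["variant_id"])}
    best, best_d = None, np.inf
    for vid in candidate_ids:
        d = abs(af[idx[vid]] - 0.02)
        if 0.005 <= af[idx[vid]] <= 0.05 and d < best_d:
            best, best_d = vid, d
    return best


def _window_counts(counts: pd.DataFrame, window) -> dict:
    out = {}
    for pop in ("founder", "outbred"):
        with np.errstate(invalid="ignore", divide="ignore"):
            q = counts[f"ac_{pop}"] / counts[f"an_{pop}"].replace(0, np.nan)
        in_win = (q >= window[0]) & (q <= window[1])
        for cls, key in (("lof", "lof"), ("synonymous", "syn")):
            out[f"{key}_{pop}"] = int(((counts["var_class"] == cls) & in_win).sum())
    return out


def _reference_concordance(reference: SyntheticCohort, j: int, rng, threshold: float):
    """Split the reference cohort in two halves and test allele-count concordance."""
    col = reference.dosages[:, j]
    called = np.flatnonzero(col != SyntheticCohort.MISSING)
    half = rng.permutation(called)
    a, b = half[: len(half) // 2], half[len(half) // 2 :]
    ca = (int(col[a].sum()), int(2 * len(a) - col[a].sum()))
    cb = (int(col[b].sum()), int(2 * len(b) - col[b].sum()))
    return lofselect.nfe_concordance_test(ca, cb, threshold=threshold)


def _association_scan(cohort: SyntheticCohort, accepted, config: RunConfig, seed: int):
    """INT + OLS scan of accepted variants in a discovery/replication split."""
    pheno = cohort.phenotypes
    traits = [c for c in pheno.columns if c not in ("sample_id", "sex", "age", "event", "time")]
    rng = stage_rng(seed, "split")
    order = rng.permutation(cohort.n_samples)
    n_disc = int(round(config.discovery_fraction * cohort.n_samples))
    splits = {"discovery": order[:n_disc], "replication": order[n_disc:]}
    idx = {v: j for j, v in enumerate(cohort.variants["variant_id"])}
    results = {"discovery": [], "replication": []}
    for name, rows in splits.items():
        sex = pheno["sex"].to_numpy()[rows]
        age = pheno["age"].to_numpy()[rows]
        for trait in traits:
            z = assoc.int_transform(pheno[trait].to_numpy()[rows], sex, age)
            for d in accepted:
                dos = cohort.dosages[rows, idx[d.variant_id]]
                try:
                    results[name].append(
                        assoc.linear_assoc(dos, z, variant_id=d.variant_id, trait_id=trait)
                    )
                except assoc.AssociationError as exc:
                    logger.info("%s: skipping %s x %s (%s)", name, d.variant_id, trait, exc)
    return results["discovery"], results["replication"], traits
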