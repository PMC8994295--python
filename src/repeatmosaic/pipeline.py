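"""End-to-end orchestration: simulate -> size -> index -> SP-PCR -> stats.

``measure_cohort`` is the in-memory bridge used throughout the package and
tests: it renders each simulated tissue distribution as a trace, re-sizes it
through the calibration, and computes instability indices, yielding a tidy
cohort table.  ``run_pipeline`` drives a full run from a ``RunConfig`` and
writes versioned CSV outputs plus a machine-readable manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohortstats, instability, simcore, smolecule, traceio

__all__ = ["RunConfig", "measure_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full pipeline run.

    Every constant defaults to the assay's standard value: 5% relative
    peak-height threshold, 1/3 target negative-well fraction, 150 RFU
    minimum sized-peak height, 72 DNA + 18 no-DNA wells per plate, and the
    12-measure / 6-tissue heatmap exclusion rules.  All are overridable from
    YAML.
    """

    seed: int = 0
    simulate: bool = True
    n_individuals: int = 14
    n_cells: int = 300
    threshold_fraction: float = 0.05
    titration_target_fraction: float = 1.0 / 3.0
    min_peak_height: float = 150.0
    wells_per_dilution: int = 72
    n_no_dna: int = 18
    dilution_means: tuple[float, ...] = (0.33, 1.1, 3.3)
    min_measures_per_tissue: int = 12
    min_tissues_per_individual: int = 6
    height_cv: float = 0.1
    peaks_path: str | None = None  # real-data inputs when simulate=False
    cohort_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "dilution_means" in raw:
            raw["dilution_means"] = tuple(float(v) for v in raw["dilution_means"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilution_means"] = list(self.dilution_means)
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def measure_cohort(
    individuals,
    stutter: simcore.StutterModel | None = None,
    calib: traceio.SizeCalibration | None = None,
    threshold_fraction: float = 0.05,
    height_cv: float = 0.1,
    seed=0,
) -> pd.DataFrame:
    """Trace, size and index every tissue of every individual.

    Returns a tidy cohort table (one row per individual x tissue) with the
    called modal repeat length, instability indices and phenotype columns.
    """
    stutter = stutter or simcore.StutterModel()
    calib = calib or traceio.default_calibration()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for ind in individuals:
        for tissue, dist in ind.tissue_distributions.items():
            trace = simcore.simulate_trace(
                dist, stutter, calib, seed=rng,
                sample_id=f"{ind.individual_id}:{tissue}", height_cv=height_cv,
            )
            called = traceio.call_distribution(trace, calib)
            res = instability.expansion_index(called, threshold_fraction)
            rows.append(
                {
                    "individual_id": ind.individual_id,
                    "tissue": tissue,
                    "locus": dist.locus,
                    "repeat_length": res.modal_repeat,
                    "expansion_index": res.expansion_index,
                    "contraction_index": res.contraction_index,
                    "instability_index": res.instability_index,
                    "peaks_retained": res.peaks_retained,
                    "aao": ind.aao,
                    "aad": ind.aad,
                }
            )
    return pd.DataFrame(rows)


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"].append({"stage": name, **counts})
    logger.info("stage %s: %s", name, counts)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full pipeline and write outputs + manifest under ``out_dir``.

    Deterministic given ``config.seed``.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "stages": [],
    }
    calib = traceio.default_calibration()
    stutter = simcore.StutterModel()
    rng = np.random.default_rng(config.seed)

    if not config.simulate:
        raise NotImplementedError(
            "real-data ingestion goes through the library API (read_peak_table / "
            "read_plate_csv); run_pipeline currently orchestrates simulated runs"
        )

    profiles = simcore.default_tissue_profiles()
    cohort_cfg = simcore.CohortConfig(
        n_individuals=config.n_individuals,
        seed=int(rng.integers(2**31)),
        n_cells=config.n_cells,
    )
    individuals = simcore.simulate_cohort(cohort_cfg, profiles)
    simcore.write_cohort_csv(individuals, out / "cohort.csv")
    simcore.write_ground_truth_yaml(cohort_cfg, profiles, out / "ground_truth.yaml",
                                    stutter=stutter)
    _stage(manifest, "simulate", n_individuals=len(individuals),
           n_tissues=len(profiles))

    # size traces + indices
    tables = []
    for ind in individuals:
        for tissue, dist in ind.tissue_distributions.items():
            tables.append(
                simcore.simulate_trace(dist, stutter, calib, seed=rng,
                                       sample_id=f"{ind.individual_id}:{tissue}",
                                       height_cv=config.height_cv)
            )
    traceio.write_peak_table_csv(tables, out / "peaks.csv")
    n_peaks = sum(len(t) for t in tables)
    _stage(manifest, "size_traces", n_traces=len(tables), n_peaks=n_peaks)

    rows = []
    for table in tables:
        called = traceio.call_distribution(table, calib)
        res = instability.expansion_index(called, config.threshold_fraction)
        ind_id, tissue = table.sample_id.split(":", 1)
        rows.append(
            {
                "sample_id": table.sample_id,
                "individual_id": ind_id,
                "tissue": tissue,
                "locus": table.locus,
                "modal_repeat": res.modal_repeat,
                "expansion_index": res.expansion_index,
                "contraction_index": res.contraction_index,
                "instability_index": res.instability_index,
                "peaks_retained": res.peaks_retained,
            }
        )
    indices = pd.DataFrame(rows)
    indices.to_csv(out / "indices.csv", index=False)
    _stage(manifest, "expansion_index", n_indexed=len(indices))
    if len(indices) != len(tables):
        raise RuntimeError("manifest reconciliation failed: indexed != traces sized")

    # single-molecule SP-PCR on the first individual, all tissues
    first = individuals[0]
    plate_rows, class_tables = [], []
    all_plates = []
    for tissue, dist in first.tissue_distributions.items():
        series = simcore.simulate_dilution_series(
            dist, config.dilution_means, config.wells_per_dilution,
            seed=rng, n_no_dna=config.n_no_dna,
            sample_id=first.individual_id, tissue=tissue,
        )
        all_plates.extend(series.plates)
        best = smolecule.select_single_molecule_dilution(
            series, config.titration_target_fraction
        )
        chosen = [p for p in series.plates if p.dilution_id == best]
        qc = [smolecule.qc_plate(p, config.titration_target_fraction,
                                 config.min_peak_height) for p in chosen]
        kept = [p for p, q in zip(chosen, qc) if q.passed]
        if not kept:
            kept = chosen  # simulated plates can narrowly miss QC; report anyway
        keptset = smolecule.PlateSet(tuple(kept), first.individual_id, tissue)
        est = smolecule.estimate_lambda_from_plate(kept[0])
        counts = smolecule.tabulate_alleles(keptset, label=tissue)
        summ = smolecule.summarize_sample(keptset)
        class_tables.append(counts)
        plate_rows.append(
            {
                "individual_id": first.individual_id,
                "tissue": tissue,
                "selected_dilution": best,
                "lambda_hat": est.lambda_hat,
                "lambda_ci_low": est.ci_low,
                "lambda_ci_high": est.ci_high,
                "n_wells": est.n_wells,
                "n_negative": est.n_negative,
                "n_contracted": counts.n_contracted,
                "n_modal": counts.n_modal,
                "n_expanded": counts.n_expanded,
                **summ.as_dict(),
            }
        )
    smolecule.write_plate_csv(
        smolecule.PlateSet(tuple(all_plates), first.individual_id),
        calib, out / "plates.csv",
    )
    summary = pd.DataFrame(plate_rows)
    summary.to_csv(out / "spcr_summary.csv", index=False)
    chi = smolecule.compare_class_counts(class_tables)
    _stage(manifest, "spcr", n_tissues=len(plate_rows),
           n_wells_sized=int(summary["n_alleles"].sum()),
           chi2=round(chi.statistic, 4), chi2_df=chi.df, chi2_p=chi.p_value)

    # cohort statistics
    cohort = indices.rename(columns={"modal_repeat": "repeat_length"}).merge(
        pd.DataFrame(
            {
                "individual_id": [i.individual_id for i in individuals],
                "aao": [i.aao for i in individuals],
                "aad": [i.aad for i in individuals],
            }
        ),
        on="individual_id",
    )
    reg_rows = []
    cereb = cohort[cohort["tissue"] == "cerebellum"]
    for response in ("aao", "aad", "duration"):
        try:
            res = cohortstats.fit_length_phenotype(cereb, response)
        except ValueError:
            continue
        reg_rows.append({"response": response, **asdict_result(res)})
    per_tissue = cohortstats.index_length_regression_per_tissue(cohort)
    for tissue, res in per_tissue.items():
        reg_rows.append({"response": f"expansion_index[{tissue}]",
                         **asdict_result(res)})
    pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
    pmat = cohortstats.pairwise_tissue_tests(cohort)
    pmat.to_csv(out / "pairwise_p.csv")
    try:
        hm = cohortstats.heatmap_cluster(
            cohort,
            min_measures_per_tissue=config.min_measures_per_tissue,
            min_tissues_per_individual=config.min_tissues_per_individual,
        )
        hm.matrix.to_csv(out / "scaled_matrix.csv")
        pd.Series(hm.column_clusters, name="cluster").rename_axis("tissue").to_csv(
            out / "tissue_clusters.csv"
        )
        n_clustered = hm.matrix.shape[0]
    except ValueError as exc:
        logger.warning("heatmap clustering skipped: %s", exc)
        n_clustered = 0
    _stage(manifest, "cohort_stats", n_regressions=len(reg_rows),
           n_individuals_clustered=n_clustered)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def asdict_result(res: cohortstats.RegressionResult) -> dict:
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r_squared": res.r_squared,
        "p_value": res.p_value,
        "n": res.n,
        "slope_se": res.slope_se,
    }
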