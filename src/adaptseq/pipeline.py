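"""End-to-end orchestration: simulate -> parse -> normalize -> stats -> classify.

A run is driven by a single config mapping (YAML/JSON) with a master seed;
every stage derives its own seed stream from it, so re-running an identical
config reproduces identical artifacts.  Each stage reads the documented
text formats the previous stage writes, so stages are independently
runnable (and independently testable) from the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import counts as cnt
from . import simulate as sim
from . import stats as st
from .design import LibraryDesign, default_design
from .reads import parse_fastq

logger = logging.getLogger("adaptseq")

STAGES = ("simulate", "parse", "normalize", "concordance", "stats", "classify", "report")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "adaptseq_run",
    "stages": list(STAGES),
    "simulate": {
        "n_sequences": 300,
        "n_targets": 100,
        "patients": {"cancer": 5, "biopsy_negative": 3, "healthy": 3},
        "n_replicates": 2,
        "depth": 10000,
        "error_rate": 0.0,
        "frac_informative_targets": 0.2,
        "effect_fold": 1.6,
        "bio_sdlog": 0.4,
        "replicate_overdispersion": 0.02,
    },
    "parse": {"anchor_mismatch_tol": 1, "index_mismatch_tol": 1, "q30_threshold": 0.85},
    "stats": {"alpha": 0.05, "n_perm": 200},
    "classify": {"n_trees": 200, "n_perm": 49, "alpha": 0.05, "fc_threshold": 1.2},
}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Merge a YAML/JSON config file and overrides over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, dict(overrides))
    unknown = set(cfg.get("stages", [])) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    return cfg


def _deep_update(base: dict, extra: Mapping) -> None:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _design_to_json(design: LibraryDesign, path: Path) -> None:
    d = dataclasses.asdict(design)
    d["stagger_offsets"] = sorted(design.stagger_offsets)
    path.write_text(json.dumps(d, indent=2))


def _design_from_json(path: Path) -> LibraryDesign:
    d = json.loads(path.read_text())
    d["stagger_offsets"] = frozenset(d["stagger_offsets"])
    return LibraryDesign(**d)


def _seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def stage_simulate(cfg: dict, outdir: Path) -> None:
    """Generate a profiling study: library, patients, counts, FASTQ, truth."""
    p = cfg["simulate"]
    seeds = _seeds(cfg["seed"], 6 + 10 * sum(p["patients"].values()))
    lib, plasma_base, aff = sim.default_profiling_system(
        n_sequences=p["n_sequences"], n_targets=p["n_targets"], seed=seeds[0]
    )
    rng = np.random.default_rng(seeds[1])
    n_informative = int(round(p["frac_informative_targets"] * p["n_targets"]))
    informative = rng.choice(p["n_targets"], size=n_informative, replace=False)
    cancer_abund = plasma_base.target_abundances.copy()
    cancer_abund[informative] *= p["effect_fold"]
    plasma_by_cohort = {
        "cancer": sim.PlasmaModel("cancer", cancer_abund, plasma_base.shared_mask),
        "biopsy_negative": dataclasses.replace(plasma_base, cohort="biopsy_negative"),
        "healthy": dataclasses.replace(plasma_base, cohort="healthy"),
    }

    counts: dict[str, dict[str, int]] = {}
    sheet_rows = []
    k = 2
    for cohort, n_pat in p["patients"].items():
        for i in range(n_pat):
            pid = f"{cohort[:3]}{i:02d}"
            patient = sim.make_patient(
                plasma_by_cohort[cohort],
                pid,
                bio_sdlog=p["bio_sdlog"],
                replicate_overdispersion=p["replicate_overdispersion"],
                seed=seeds[k],
            )
            k += 1
            mat = sim.simulate_patient_counts(
                lib, patient, aff, depth=p["depth"], seed=seeds[k],
                n_replicates=p["n_replicates"],
            )
            k += 1
            for r in range(p["n_replicates"]):
                sid = f"{pid}_r{r + 1}"
                counts[sid] = dict(zip(lib.sequences, mat[:, r].tolist()))
                sheet_rows.append(
                    {"sample_id": sid, "cohort": cohort, "patient_id": pid,
                     "replicate": r + 1}
                )

    sheet = pd.DataFrame(sheet_rows)
    design = default_design(sheet["sample_id"].tolist(), index_seed=seeds[-1])
    sheet["index_i7"] = sheet["sample_id"].map(design.i7_indices)
    sheet = sheet[["sample_id", "index_i7", "cohort", "patient_id", "replicate"]]
    sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    _design_to_json(design, outdir / "design.json")

    table = cnt.CountTable.from_sample_counts(
        counts, samples=sheet.set_index("sample_id")
    )
    table.to_tsv(outdir / "true_counts.tsv")
    n = sim.write_fastq(
        table, design, outdir / "reads.fastq",
        error_rate=p["error_rate"], seed=seeds[-2],
    )
    truth = {
        "informative_targets": sorted(int(t) for t in informative),
        "sequence_target": {s: int(t) for s, t in zip(lib.sequences, aff.target_of)},
        "n_reads_written": n,
        "seed": cfg["seed"],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    logger.info("simulate: %d samples, %d reads", len(counts), n)


def stage_parse(cfg: dict, outdir: Path) -> None:
    design = _design_from_json(outdir / "design.json")
    sheet = cnt.load_sample_sheet(outdir / "sample_sheet.csv")
    pp = cfg["parse"]
    result = parse_fastq(
        outdir / "reads.fastq",
        design,
        sample_sheet={row.index_i7: sid for sid, row in sheet.iterrows()},
        anchor_mismatch_tol=pp["anchor_mismatch_tol"],
        index_mismatch_tol=pp["index_mismatch_tol"],
        q30_threshold=pp["q30_threshold"],
    )
    table = cnt.CountTable.from_sample_counts(result.counts, samples=sheet)
    table.to_tsv(outdir / "counts.tsv")
    result.write_qc_json(outdir / "qc.json")
    logger.info(
        "parse: %d reads, %d valid, %d invalid, %d unassigned",
        result.run_qc.total_reads, result.run_qc.valid_reads,
        result.invalid_reads, result.unassigned_reads,
    )


def stage_normalize(cfg: dict, outdir: Path) -> None:
    sheet = cnt.load_sample_sheet(outdir / "sample_sheet.csv")
    table = cnt.CountTable.from_tsv(outdir / "counts.tsv", samples=sheet)
    norm = cnt.normalize_counts(table)
    norm.to_tsv(outdir / "normalized.tsv")
    logger.info("normalize: global mean %.1f", norm.global_mean)


def _load_normalized(outdir: Path) -> cnt.NormalizedTable:
    sheet = cnt.load_sample_sheet(outdir / "sample_sheet.csv")
    df = pd.read_csv(outdir / "normalized.tsv", sep="\t").set_index("sequence")
    return cnt.NormalizedTable(
        data=df, samples=sheet.loc[df.columns], global_mean=float(df.sum(axis=0).mean())
    )


def stage_concordance(cfg: dict, outdir: Path) -> None:
    norm = _load_normalized(outdir)
    pairs = cnt.infer_pairs(norm.samples, max_inter_pairs=50)
    conc = cnt.replicate_concordance(norm, pairs)
    conc.to_csv(outdir / "concordance.csv", index=False)
    logger.info("concordance:\n%s", cnt.concordance_summary(conc))


def _patient_profiles(norm: cnt.NormalizedTable) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse technical replicates to one mean profile per patient."""
    meta = norm.samples
    prof = norm.data.T.groupby(meta["patient_id"]).mean()
    cohorts = meta.groupby("patient_id")["cohort"].first().loc[prof.index]
    return prof, cohorts


def stage_stats(cfg: dict, outdir: Path) -> None:
    norm = _load_normalized(outdir)
    prof, cohorts = _patient_profiles(norm)
    sp = cfg["stats"]
    seeds = _seeds(cfg["seed"] + 1, 2)
    perm = st.significance_permutation_test(
        prof.T, cohorts.to_numpy(), alpha=sp["alpha"], n_perm=sp["n_perm"], seed=seeds[0]
    )
    perm.to_json(outdir / "anova_permutation.json")
    y = np.where(cohorts.to_numpy() == "cancer", "cancer", "control")
    tests = st.two_group_tests(prof.T, y, group_order=("cancer", "control"))
    tests.insert(0, "sequence", tests.index)
    tests.to_csv(outdir / "two_group_tests.tsv", sep="\t", index=False)
    logger.info("stats: observed=%d p=%.4g", int(perm.observed), perm.p_value)


def stage_classify(cfg: dict, outdir: Path) -> None:
    norm = _load_normalized(outdir)
    prof, cohorts = _patient_profiles(norm)
    cp = cfg["classify"]
    seeds = _seeds(cfg["seed"] + 2, 2)
    y = np.where(cohorts.to_numpy() == "cancer", "cancer", "control")
    perm, rf = cls.auc_permutation_test(
        prof, y, n_perm=cp["n_perm"], seed=seeds[0],
        alpha=cp["alpha"], fc_threshold=cp["fc_threshold"], n_trees=cp["n_trees"],
    )
    rf.to_json(outdir / "rf_cancer_vs_all.json")
    perm.to_json(outdir / "auc_permutation.json")
    comparisons = [
        ("cancer_vs_biopsy_negative", "cancer", "biopsy_negative"),
        ("cancer_vs_healthy", "cancer", "healthy"),
        ("cancer_vs_all_controls", "cancer", ["biopsy_negative", "healthy"]),
    ]
    present = set(cohorts)
    comparisons = [
        c for c in comparisons
        if set([c[1]] if isinstance(c[1], str) else c[1]) <= present
        and set([c[2]] if isinstance(c[2], str) else c[2]) & present
    ]
    sub = cls.subgroup_analyses(
        prof, pd.DataFrame({"cohort": cohorts}), comparisons,
        n_trees=cp["n_trees"], seed=seeds[1],
    )
    summary = pd.DataFrame(
        [{"comparison": k, "oob_auc": v.auc, "n_features": len(v.selected_features)}
         for k, v in sub.items()]
    )
    summary.to_csv(outdir / "subgroup_auc.csv", index=False)
    logger.info("classify: OOB AUC %.3f (perm p %.4g)", rf.auc, perm.p_value)


def generate_report(outdir: str | Path) -> dict:
    """Aggregate stage artifacts into one report; never recomputes.

    Missing artifacts are listed as absent rather than fabricated.
    """
    outdir = Path(outdir)
    report: dict[str, Any] = {"outdir": str(outdir), "sections": {}}

    def load_json(name):
        f = outdir / name
        return json.loads(f.read_text()) if f.exists() else None

    qc = load_json("qc.json")
    report["sections"]["qc"] = qc if qc is not None else "absent"
    conc_file = outdir / "concordance.csv"
    if conc_file.exists():
        conc = pd.read_csv(conc_file)
        report["sections"]["concordance"] = cnt.concordance_summary(conc).to_dict("records")
    else:
        report["sections"]["concordance"] = "absent"
    for key, fname in [
        ("anova_permutation", "anova_permutation.json"),
        ("auc_permutation", "auc_permutation.json"),
        ("rf", "rf_cancer_vs_all.json"),
    ]:
        payload = load_json(fname)
        if payload is not None and key in ("anova_permutation", "auc_permutation"):
            payload = {k: payload[k] for k in ("observed", "p_value", "n_perm", "seed")}
        if payload is not None and key == "rf":
            payload = {
                "auc": payload["auc"], "n_trees": payload["n_trees"],
                "n_features": len(payload["selected_features"]),
                "permutation_p": payload.get("permutation_p"),
            }
        report["sections"][key] = payload if payload is not None else "absent"
    sub_file = outdir / "subgroup_auc.csv"
    report["sections"]["subgroups"] = (
        pd.read_csv(sub_file).to_dict("records") if sub_file.exists() else "absent"
    )
    truth = load_json("ground_truth.json")
    if truth is not None:
        report["sections"]["simulation"] = {
            "n_reads_written": truth["n_reads_written"], "seed": truth["seed"],
        }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "parse": stage_parse,
    "normalize": stage_normalize,
    "concordance": stage_concordance,
    "stats": stage_stats,
    "classify": stage_classify,
}


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Execute the enabled stages in order; returns the aggregated report.

    A stage failure halts the run with the failing stage named.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_echo.json").write_text(json.dumps(cfg, indent=2, default=str))
    for stage in STAGES:
        if stage == "report" or stage not in cfg["stages"]:
            continue
        logger.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    if "report" in cfg["stages"]:
        return generate_report(outdir)
    return {"outdir": str(outdir), "sections": {}}
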