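"""End-to-end orchestration: QC -> distances -> gap -> identification ->
MOTU -> concordance -> IBD -> NJ tree, driven by one declarative config.

Every run directory contains ``manifest.json`` recording each parameter
actually used (so every number in every report is reproducible from the
manifest plus the inputs alone) and ``summary.json`` with the headline
quantities.  A single global seed fans out to per-stage streams derived from
the stage name, so toggling one stage does not shift another's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import concordance as conc
from . import gap_analysis as gap
from . import geodist, identification, motu, njtree, seqio
from .distances import distance_matrix

logger = logging.getLogger("barcodekit")

ALL_STAGES = ("qc", "distances", "gap", "identification", "motu", "concordance", "ibd", "tree")
#: stages whose failure aborts the run (the rest are logged and skipped)
REQUIRED_STAGES = ("qc", "distances")


@dataclass
class RunConfig:
    fasta: str = ""
    metadata: str = ""
    output_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    model: str = "K2P"
    column_mapping: dict = field(default_factory=dict)
    min_length: int = 500
    max_ambiguous_frac: float = 0.01
    whitelist: tuple[str, ...] = ()
    bold_threshold: float = 0.01
    density_fallback_threshold: float = 0.01
    abgd_P_grid: tuple[float, ...] = tuple(np.geomspace(0.001, 0.1, 15).round(5))
    abgd_X_values: tuple[float, ...] = (1.5, 1.0)
    tcs_limits: tuple[float, ...] = tuple(np.arange(0.90, 1.0, 0.01).round(2))
    resl_seed_threshold: float = 0.022
    resl_refine_range: tuple[float, float] = (0.007, 0.022)
    ibd_min_n: int = 10
    ibd_min_span_km: float = 275.0
    ibd_n_perm: int = 999
    ibd_alpha: float = 0.05
    bootstrap_reps: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "whitelist", "abgd_P_grid", "abgd_X_values", "tcs_limits"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "resl_refine_range" in raw:
            raw["resl_refine_range"] = tuple(raw["resl_refine_range"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, dataset: seqio.BarcodeDataset | None = None) -> Path:
    """Execute the enabled stages; returns the run directory.

    ``dataset`` may be passed directly (e.g. a freshly generated synthetic
    library) instead of reading ``config.fasta``/``config.metadata``.
    """
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    summary: dict = {}
    manifest = {"parameters": dataclasses.asdict(config), "stages_run": []}

    try:
        if dataset is None:
            dataset = seqio.read_fasta_with_metadata(
                config.fasta, config.metadata, column_mapping=config.column_mapping
            )
        ds, rejections = seqio.qc_filter(
            dataset,
            min_length=config.min_length,
            max_ambiguous_frac=config.max_ambiguous_frac,
            whitelist=config.whitelist,
        )
        if "qc" in config.stages:
            seqio.write_dataset(ds, outdir / "filtered.fasta", outdir / "filtered_metadata.tsv")
            rejections.to_csv(outdir / "rejections.tsv", sep="\t", index=False)
            manifest["stages_run"].append("qc")
        summary["n_sequences"] = len(ds)
        summary["n_rejected"] = len(rejections)
        labels = ds.species_map()
        genus = {sid: ds[sid].genus for sid in ds.ids}
        summary["n_species"] = len({v for v in labels.values() if v})

        dm = distance_matrix(ds, model=config.model)
        if "distances" in config.stages:
            dm.to_square_tsv(outdir / "distances_square.tsv")
            dm.to_long_tsv(outdir / "distances_long.tsv")
            manifest["stages_run"].append("distances")

        thresholds: dict[str, float] = {}
        if {"gap", "identification"} & set(config.stages):
            try:
                _stage_gap(config, outdir, dm, labels, genus, summary, manifest, thresholds)
            except Exception:
                logger.exception("gap stage failed; skipped")
        if "identification" in config.stages:
            _optional(config, "identification", manifest, lambda: _stage_ident(
                config, outdir, dm, labels, summary, thresholds))
        partitions: list[motu.Partition] = []
        if {"motu", "concordance"} & set(config.stages):
            try:
                _stage_motu(config, outdir, ds, dm, summary, partitions)
                if "motu" in config.stages:
                    manifest["stages_run"].append("motu")
            except Exception:
                logger.exception("motu stage failed; skipped")
        if "concordance" in config.stages:
            _optional(config, "concordance", manifest, lambda: _stage_concordance(
                config, outdir, dm, labels, summary, partitions, thresholds))
        if "ibd" in config.stages:
            _optional(config, "ibd", manifest, lambda: _stage_ibd(
                config, outdir, ds, dm, summary))
        if "tree" in config.stages:
            _optional(config, "tree", manifest, lambda: _stage_tree(
                config, outdir, ds, dm, labels, summary))
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return outdir


def _optional(config, stage, manifest, fn) -> None:
    try:
        fn()
        manifest["stages_run"].append(stage)
    except Exception:
        logger.exception("optional stage %r failed; skipped", stage)


def _stage_gap(config, outdir, dm, labels, genus, summary, manifest, thresholds) -> None:
    summaries = gap.divergence_summaries(dm, labels, genus)
    profile = gap.gap_profile(dm, labels)
    q95, q05 = gap.empirical_thresholds(dm, labels, genus)
    thresholds["q95_intra"] = q95
    if "gap" in config.stages:
        summaries.as_frame().to_csv(outdir / "divergence_summaries.tsv", sep="\t", index=False)
        profile.per_sequence.to_csv(outdir / "gap_per_sequence.tsv", sep="\t", index=False)
        profile.per_species.to_csv(outdir / "gap_per_species.tsv", sep="\t", index=False)
        with open(outdir / "thresholds.json", "w") as fh:
            json.dump({"q95_intra": q95, "q05_congeneric": q05}, fh, indent=1)
        _gap_scatter_plot(profile, q95, q05, outdir / "gap_scatter.png")
        manifest["stages_run"].append("gap")
    if summaries.intraspecific:
        summary["mean_intraspecific_pct"] = 100 * summaries.intraspecific["mean"]
        summary["n_intraspecific_comparisons"] = summaries.intraspecific["n_comparisons"]
    if summaries.congeneric:
        summary["mean_congeneric_pct"] = 100 * summaries.congeneric["mean"]
        summary["n_congeneric_comparisons"] = summaries.congeneric["n_comparisons"]
    summary["q95_intra_pct"] = 100 * q95
    summary["q05_congeneric_pct"] = 100 * q05
    verdicts = profile.per_species.dropna(subset=["gap_present"])
    if len(verdicts):
        summary["gap_present_pct"] = 100.0 * verdicts["gap_present"].mean()


def _gap_scatter_plot(profile, q95, q05, path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is a convenience, never a hard dependency
        return
    df = profile.per_sequence.dropna(subset=["max_conspecific", "nn_distance"])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(100 * df["max_conspecific"], 100 * df["nn_distance"], s=8, alpha=0.5)
    lim = max(100 * df[["max_conspecific", "nn_distance"]].max().max(), 1.0)
    ax.plot([0, lim], [0, lim], "k-", lw=0.8)
    ax.axvline(100 * q95, ls="--", c="grey")
    ax.axhline(100 * q05, ls="--", c="grey")
    ax.set_xlabel("max intraspecific distance (%)")
    ax.set_ylabel("nearest neighbor distance (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage_ident(config, outdir, dm, labels, summary, thresholds) -> None:
    minimizers, curve = identification.threshold_cumulative_error(dm, labels)
    thresholds["cumulative_error"] = identification.optimal_threshold(minimizers)
    try:
        thresholds["density_minimum"] = identification.threshold_density_minimum(dm)
    except (identification.NoDensityMinimumError, ValueError):
        logger.warning("no density minimum; falling back to configured default")
        thresholds["density_minimum"] = config.density_fallback_threshold
    thresholds["bold_1pct"] = config.bold_threshold

    panel = identification.run_identification_panel(dm, labels, thresholds)
    curve.to_csv(outdir / "cumulative_error_curve.tsv", sep="\t", index=False)
    panel.counts.to_csv(outdir / "panel_counts.tsv", sep="\t")
    panel.percents.to_csv(outdir / "panel_percents.tsv", sep="\t")
    all_outcomes = []
    for (crit, name), tab in panel.outcome_tables.items():
        tab = tab.copy()
        tab["threshold_name"] = name
        all_outcomes.append(tab)
    import pandas as pd

    pd.concat(all_outcomes).to_csv(outdir / "identification_outcomes.tsv", sep="\t", index=False)
    summary["n_queries"] = panel.n_queries
    summary["bm_correct_pct"] = float(panel.percents.loc["correct", ("BM", "-")])
    for name in thresholds:
        for crit in ("BCM", "BIC"):
            summary[f"{crit.lower()}_correct_pct_{name}"] = float(
                panel.percents.loc["correct", (crit, name)]
            )
    summary["threshold_cumulative_error_pct"] = 100 * thresholds["cumulative_error"]
    summary["threshold_density_minimum_pct"] = 100 * thresholds["density_minimum"]
    summary["threshold_q95_intra_pct"] = 100 * thresholds.get("q95_intra", np.nan)


def _stage_motu(config, outdir, ds, dm, summary, partitions) -> None:
    import pandas as pd

    write = "motu" in config.stages
    if write:
        scan = motu.abgd_scan(dm, config.abgd_P_grid, config.abgd_X_values)
        scan.to_csv(outdir / "abgd_scan.tsv", sep="\t", index=False)

    mid_P = float(np.median(config.abgd_P_grid))
    partitions.append(motu.abgd_partition(dm, P=mid_P, X=config.abgd_X_values[0]))
    partitions.append(motu.abgd_recursive(dm, P=mid_P, X=config.abgd_X_values[0]))
    for limit in (0.95,):
        partitions.append(motu.tcs_cluster(ds, limit=limit))
    partitions.append(
        motu.resl_like_cluster(
            dm,
            seed_threshold=config.resl_seed_threshold,
            refine_range=config.resl_refine_range,
        )
    )
    if write:
        pd.concat([p.as_frame() for p in partitions]).to_csv(
            outdir / "partitions.tsv", sep="\t", index=False
        )
        counts = pd.DataFrame(
            [{"method": p.method, "params": repr(p.params), "n_motus": p.n_motus} for p in partitions]
        )
        counts.to_csv(outdir / "motu_counts.tsv", sep="\t", index=False)
    for p in partitions:
        summary[f"n_motus_{p.method}"] = p.n_motus


def _stage_concordance(config, outdir, dm, labels, summary, partitions, thresholds) -> None:
    import pandas as pd

    if not partitions:
        raise RuntimeError("concordance requires the motu stage results")
    frames = []
    for p in partitions:
        rep = conc.classify_species(p, labels)
        per = rep.per_species.copy()
        per["method"] = p.method
        frames.append(per)
        for cat in conc.CATEGORIES:
            summary[f"{cat.lower()}_pct_{p.method}"] = rep.percent(cat)
    pd.concat(frames).to_csv(outdir / "concordance_per_species.tsv", sep="\t", index=False)

    cutoff = thresholds.get("q95_intra")
    if cutoff:
        deep = conc.flag_deep_divergence(dm, labels, cutoff)
        deep.to_csv(outdir / "deep_divergence.tsv", sep="\t", index=False)
        summary["n_deep_divergent_species"] = len(deep)


def _stage_ibd(config, outdir, ds, dm, summary) -> None:
    table, sig = geodist.ibd_screen(
        ds,
        dm,
        min_n=config.ibd_min_n,
        min_span_km=config.ibd_min_span_km,
        n_perm=config.ibd_n_perm,
        alpha=config.ibd_alpha,
        seed=config.stage_seed("ibd"),
    )
    table.to_csv(outdir / "ibd_results.tsv", sep="\t", index=False)
    summary["n_ibd_species_tested"] = len(table)
    summary["n_ibd_significant"] = sig


def _stage_tree(config, outdir, ds, dm, labels, summary) -> None:
    tree, support = njtree.bootstrap_support(
        ds, model=config.model, n_reps=config.bootstrap_reps, seed=config.stage_seed("tree")
    )
    tree.write(str(outdir / "nj_tree.nwk"))
    if support:
        summary["mean_bootstrap_support"] = float(np.mean(list(support.values())))
    singles = gap.assess_singletons(dm, labels, tree)
    singles.to_csv(outdir / "singleton_assessment.tsv", sep="\t", index=False)
    if len(singles):
        summary["singletons_distinguishable_pct"] = 100.0 * singles["distinguishable"].mean()


def regression_report(run_dir, expectations_file) -> "pd.DataFrame":
    """Compare a completed run's summary against expected values.

    The expectations file is JSON: ``{key: {"expected": v, "tol": t}}`` with
    keys matching ``summary.json``.  Returns a table with observed, expected,
    tolerance and pass/fail per expectation.
    """
    import pandas as pd

    with open(Path(run_dir) / "summary.json") as fh:
        summary = json.load(fh)
    with open(expectations_file) as fh:
        expectations = json.load(fh)
    rows = []
    for key, spec in expectations.items():
        if "expected" not in spec:
            raise ValueError(f"expectation {key!r} missing 'expected'")
        expected = float(spec["expected"])
        tol = float(spec.get("tol", 0.0))
        observed = summary.get(key)
        ok = observed is not None and abs(float(observed) - expected) <= tol
        rows.append(
            {"key": key, "observed": observed, "expected": expected, "tol": tol, "pass": bool(ok)}
        )
    return pd.DataFrame(rows, columns=["key", "observed", "expected", "tol", "pass"])
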