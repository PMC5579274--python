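"""Configuration, seeding, end-to-end pipelines and the command-line interface.

The canonical flow is: ``simulate`` (phantoms + cohort tables) -> ``extract``
(1615-feature battery per scan) -> ``univariate`` (Spearman screen with FDR
control) -> ``train`` (reduction, 0.632+ forward selection, final logistic
model; optional clinical combination via partition-ensemble forest) ->
``evaluate`` (ROC metrics, concordance index, Kaplan-Meier risk groups).
A single master seed fans out deterministically to per-stage seeds, and every
run writes a manifest (config hash, seed) so identical manifests imply
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .feature_bank import FeatureTable, extract_battery
from .forest_models import assess_risk, select_staging, train_forest, tune_weight
from .image_core import load_nifti_pair, save_nifti
from .model_construction import (
    LogisticModel,
    choose_order,
    finalize_logistic,
    forward_select,
    reduce_feature_set,
)
from .stats_core import SurvivalData, concordance_index, km_logrank, roc_metrics, univariate_screen
from .synthetic_gen import PhantomSpec, make_phantom

__all__ = [
    "RunConfig",
    "stage_seed",
    "cmd_extract",
    "cmd_univariate",
    "cmd_train",
    "cmd_evaluate",
    "cli",
]


@dataclass
class RunConfig:
    """Run parameters; the defaults reproduce the reference analysis settings."""

    master_seed: int = 0
    # selection
    target_size: int = 25
    orders: int = 10
    n_boot: int = 100
    prescreen: int | None = 150
    # imbalance / tuning
    weight: float = 1.0
    tune_weights: bool = False
    splits: int = 10
    # univariate
    fdr_q: float = 0.10
    # extraction
    n_bins: int = 100
    inactive_frac: float = 0.5
    getu_a: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed combined with a CRC of the
    stage name through a SeedSequence (kept below 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def write_manifest(out_dir: Path, config: RunConfig, stage: str, extra: dict | None = None):
    manifest = {
        "stage": stage,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# pipeline stages (library surface; the CLI wraps these)


def cmd_extract(manifest_df: pd.DataFrame, out_csv, config: RunConfig | None = None) -> FeatureTable:
    """Extract the 1615-feature battery for every scan listed in a manifest.

    ``manifest_df`` columns: patient_id, volume, mask, modality.  Per-case
    failures (shape/affine mismatch, empty ROI) are collected and reported at
    the end without aborting the whole run.
    """
    config = config or RunConfig()
    if manifest_df.empty:
        raise ValueError("empty input list")
    rows, failures = {}, {}
    for _, rec in manifest_df.iterrows():
        pid = str(rec["patient_id"])
        try:
            vol, mask = load_nifti_pair(rec["volume"], rec["mask"], rec.get("modality", "PET"))
            fv = extract_battery(
                vol, mask,
                n_bins=config.n_bins,
                inactive_frac=config.inactive_frac,
                getu_a=config.getu_a,
            )
            rows[pid] = fv.to_series()
        except (ValueError, OSError) as exc:
            failures[pid] = str(exc)
    if not rows:
        raise ValueError(f"all cases failed: {failures}")
    df = pd.DataFrame(rows).T
    df.index.name = "patient_id"
    table = FeatureTable(df)
    if out_csv is not None:
        table.to_csv(out_csv, config=config.to_dict())
    if failures:
        click.echo(f"WARNING: {len(failures)} case(s) failed: {failures}", err=True)
    return table


def cmd_univariate(
    features: FeatureTable, outcomes: pd.DataFrame, outcome: str = "event", q: float = 0.10
) -> pd.DataFrame:
    """Spearman association of every feature with a binary outcome + BH flags."""
    fdf = features.df[features.feature_columns]
    unmatched = fdf.index.symmetric_difference(outcomes.index)
    if len(unmatched):
        raise ValueError(f"unmatched patient ids: {unmatched.tolist()}")
    y = outcomes.loc[fdf.index, outcome].to_numpy(dtype=int)
    results = univariate_screen(fdf, y, q=q)
    rep = pd.DataFrame(
        {
            "feature": [r.feature_name for r in results],
            "r_s": [r.r_s for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant_after_fdr for r in results],
        }
    ).set_index("feature")
    rep["family"] = [
        f.split("__")[0].split("_")[-1] if "_" in f else "other" for f in rep.index
    ]
    return rep


def cmd_train(
    table: FeatureTable,
    outcome: str = "event",
    clinical_features: tuple[str, ...] | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Radiomic model pipeline: reduce -> forward select -> choose order ->
    finalize; optionally combine with clinical variables via a forest."""
    config = config or RunConfig()
    feat_cols = [
        c for c in table.feature_columns
        if c not in ("age", "hn_type", "t_stage", "n_stage", "tnm_stage", "cohort")
    ]
    X = table.df[feat_cols]
    y = table.df[outcome].to_numpy(dtype=int)
    reduced = reduce_feature_set(
        X, y, target_size=min(config.target_size, len(feat_cols)),
        prescreen=config.prescreen,
    )
    models = forward_select(
        reduced, table.df, outcome, orders=config.orders,
        n_boot=config.n_boot, rng_seed=stage_seed(config.master_seed, "forward"),
    )
    chosen = choose_order(models)
    logistic = finalize_logistic(
        chosen.features, table.df, outcome, n_boot=config.n_boot,
        rng_seed=stage_seed(config.master_seed, "finalize"),
    )
    artifacts = {
        "logistic": logistic,
        "chosen_order": chosen.order,
        "per_order": models,
        "reduced": reduced,
        "forest": None,
        "staging": None,
        "weight": config.weight,
    }
    if clinical_features is not None:
        staging = select_staging(
            table.df, outcome, splits=config.splits, n_boot=min(config.n_boot, 20),
            rng_seed=stage_seed(config.master_seed, "staging"),
        )
        forest_feats = tuple(chosen.features) + tuple(clinical_features) + tuple(staging)
        w = config.weight
        if config.tune_weights:
            w = tune_weight(
                table.df, outcome, forest_feats, splits=config.splits,
                n_boot=min(config.n_boot, 20),
                rng_seed=stage_seed(config.master_seed, "weight"),
            )
        forest = train_forest(
            table.df, outcome, forest_feats, n_boot=config.n_boot, weight=w,
            rng_seed=stage_seed(config.master_seed, "forest"),
        )
        artifacts.update(forest=forest, staging=staging, weight=w)
    return artifacts


def cmd_evaluate(
    artifacts: dict,
    train_table: FeatureTable,
    test_table: FeatureTable,
    outcome: str = "event",
) -> dict:
    """Independent evaluation: ROC metrics at 0.5, concordance index and
    Kaplan-Meier risk stratification (2- and 3-group)."""
    train_ids = set(train_table.df.index)
    test_ids = set(test_table.df.index)
    resubstitution = train_ids == test_ids
    if not resubstitution and train_ids & test_ids:
        raise ValueError(f"subject overlap between train and test: {sorted(train_ids & test_ids)}")

    model = artifacts["forest"] if artifacts.get("forest") is not None else artifacts["logistic"]
    prob = model.predict_proba(test_table.df)
    y = test_table.df[outcome].to_numpy(dtype=int)
    roc = roc_metrics(prob, y, threshold=0.5)
    surv = SurvivalData(
        test_table.df["time_months"].to_numpy(dtype=float), y
    )
    ci = concordance_index(prob, surv)
    groups2 = assess_risk(prob, mode="two")
    groups3 = assess_risk(prob, mode="three")
    out = {
        "resubstitution": resubstitution,
        "n_test": len(test_table),
        "auc": roc.auc,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
        "accuracy": roc.accuracy,
        "concordance_index": ci,
        "risk_groups_two": dict(zip(*np.unique(groups2, return_counts=True))),
        "risk_groups_three": dict(zip(*np.unique(groups3, return_counts=True))),
        "prob_rf": prob,
    }
    try:
        km2 = km_logrank(groups2, surv)
        out["km_two_group_p"] = km2.p_value
    except ValueError as exc:
        out["km_two_group_p"] = None
        out["km_two_group_note"] = str(exc)
    if len(set(groups3)) >= 2:
        km3 = km_logrank(groups3, surv)
        out["km_three_group_p"] = km3.p_value
        out["km_three_group_pairwise"] = {f"{a}|{b}": p for (a, b), p in km3.pairwise.items()}
    return out


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.version_option(__version__)
def cli():
    """Radiomics risk-assessment workbench."""


@cli.command()
@click.option("--out-dir", type=click.Path(), required=True)
@click.option("--n-phantoms", default=10, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--grid", default=24, show_default=True, help="phantom grid size (voxels)")
def simulate(out_dir, n_phantoms, seed, grid):
    """Write synthetic phantoms (NIfTI) and a scan manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_phantoms):
        spec = PhantomSpec(
            shape=(grid, grid, grid),
            roi_axes_mm=(grid / 3.5, grid / 3.5, grid / 3.5),
            texture_corr_mm=float(rng.uniform(1.0, 4.0)),
            texture_variance=float(rng.uniform(0.5, 4.0)),
            rng_seed=int(rng.integers(2**31)),
        )
        vol, mask = make_phantom(spec)
        vpath = out / f"phantom{i:03d}_pet.nii.gz"
        mpath = out / f"phantom{i:03d}_mask.nii.gz"
        save_nifti(vpath, vol.data, vol.spacing)
        save_nifti(mpath, mask.data.astype(np.uint8), mask.spacing)
        rows.append({"patient_id": f"P{i:04d}", "volume": str(vpath), "mask": str(mpath), "modality": "PET"})
        spec_yaml = dataclasses.asdict(spec)
        (out / f"phantom{i:03d}_spec.yaml").write_text(yaml.safe_dump(spec_yaml))
    pd.DataFrame(rows).to_csv(out / "scans.csv", index=False)
    click.echo(f"wrote {n_phantoms} phantoms to {out}")


@cli.command()
@click.option("--scans", type=click.Path(exists=True), required=True, help="manifest CSV")
@click.option("--out", "out_csv", type=click.Path(), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def extract(scans, out_csv, config_path):
    """Extract the 1615-feature battery for every listed scan."""
    config = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    manifest = pd.read_csv(scans)
    table = cmd_extract(manifest, out_csv, config)
    out_dir = Path(out_csv).parent
    write_manifest(out_dir, config, "extract", {"n_cases": len(table)})
    click.echo(f"extracted {len(table)} cases x {len(table.feature_columns)} features")


@cli.command()
@click.option("--features", type=click.Path(exists=True), required=True)
@click.option("--outcomes", type=click.Path(exists=True), required=True)
@click.option("--outcome", default="event", show_default=True)
@click.option("--q", default=0.10, show_default=True)
@click.option("--out", "out_csv", type=click.Path(), required=True)
def univariate(features, outcomes, outcome, q, out_csv):
    """Univariate Spearman screen with Benjamini-Hochberg FDR control."""
    ftab = FeatureTable.from_csv(features)
    odf = pd.read_csv(outcomes, index_col="patient_id")
    rep = cmd_univariate(ftab, odf, outcome, q)
    rep.to_csv(out_csv)
    frac = rep.groupby("family")["significant"].mean()
    click.echo(f"significant fraction per family:\n{frac.to_string()}")


@cli.command()
@click.option("--table", "table_csv", type=click.Path(exists=True), required=True)
@click.option("--outcome", default="event", show_default=True)
@click.option("--clinical/--no-clinical", default=False, show_default=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out-dir", type=click.Path(), required=True)
def train(table_csv, outcome, clinical, config_path, out_dir):
    """Train the radiomic (and optionally radiomic+clinical) risk model."""
    config = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    table = FeatureTable.from_csv(table_csv)
    clin = ("age", "hn_type") if clinical else None
    artifacts = cmd_train(table, outcome, clin, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "logistic_model.json").write_text(artifacts["logistic"].to_json())
    summary = {
        "chosen_order": artifacts["chosen_order"],
        "features": list(artifacts["logistic"].features),
        "staging": list(artifacts["staging"]) if artifacts["staging"] else None,
        "weight": artifacts["weight"],
        "per_order": [
            {"order": m.order, "estimate": m.estimate, "se": m.se, "features": list(m.features)}
            for m in artifacts["per_order"]
        ],
    }
    (out / "training_summary.json").write_text(json.dumps(summary, indent=2))
    write_manifest(out, config, "train")
    click.echo(f"chosen order {artifacts['chosen_order']}: {artifacts['logistic'].features}")


@cli.command()
@click.option("--train-table", type=click.Path(exists=True), required=True)
@click.option("--test-table", type=click.Path(exists=True), required=True)
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--outcome", default="event", show_default=True)
@click.option("--out-dir", type=click.Path(), required=True)
def evaluate(train_table, test_table, model_path, outcome, out_dir):
    """Evaluate a trained model on an independent test table."""
    tr = FeatureTable.from_csv(train_table)
    te = FeatureTable.from_csv(test_table)
    model = LogisticModel.from_json(Path(model_path).read_text())
    artifacts = {"logistic": model, "forest": None}
    res = cmd_evaluate(artifacts, tr, te, outcome)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prob = res.pop("prob_rf")
    report = pd.DataFrame(
        {
            "prob_rf": prob,
            "risk_group": assess_risk(prob, mode="three"),
        },
        index=te.df.index,
    )
    report.to_csv(out / "risk_report.csv")
    (out / "evaluation.json").write_text(json.dumps(res, indent=2, default=str))
    click.echo(json.dumps({k: v for k, v in res.items() if np.isscalar(v)}, indent=2, default=str))


@cli.command()
@click.option("--evaluation", type=click.Path(exists=True), required=True)
def report(evaluation):
    """Print a short human-readable summary of an evaluation JSON."""
    res = json.loads(Path(evaluation).read_text())
    lines = [
        f"n_test = {res.get('n_test')}  (resubstitution: {res.get('resubstitution')})",
        f"AUC  {res.get('auc'):.3f}   sens {res.get('sensitivity'):.3f}   "
        f"spec {res.get('specificity'):.3f}   acc {res.get('accuracy'):.3f}",
        f"concordance index {res.get('concordance_index'):.3f}",
        f"KM two-group log-rank p = {res.get('km_two_group_p')}",
    ]
    if "km_three_group_p" in res:
        lines.append(f"KM three-group log-rank p = {res['km_three_group_p']}")
    click.echo("\n".join(lines))


if __name__ == "__main__":
    cli()
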