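"""End-to-end orchestration: file I/O, risk-label derivation, workflows.

A run goes: read (or simulate) replicate-level Ct readings -> average and
normalize against beta-actin -> fit the two-class discriminant -> score
every patient -> evaluate (confusion metrics with Wald CIs, ROC/AUC,
per-gene t-tests) -> write delimited reports. Everything is deterministic
given the run configuration.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import (
    confusion, gene_ttest_table, performance_table, roc,
)
from .panels import (
    BENIGN, CANCER, HIGHER_RISK, LOWER_RISK, PANEL14, REFERENCE_GENE,
    UNKNOWN, VALID_LABELS, GenePanel,
)
from .qda import fit_diagnoser, fit_stratifier, score_profiles
from .qpcr import normalize_table
from .simulate import SimConfig, profiles_to_raw_ct, simulate_profiles

logger = logging.getLogger(__name__)

__all__ = [
    "read_ct_table",
    "read_labels",
    "derive_risk_label",
    "select_subgroup",
    "RunConfig",
    "run_pipeline",
]

CT_COLUMNS = ("patient_id", "gene", "replicate", "ct")


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    # delimiter sniffed: comma or tab
    return pd.read_csv(path, sep=None, engine="python")


def read_ct_table(path, panel: GenePanel = PANEL14) -> pd.DataFrame:
    """Read a long-format replicate Ct table (columns patient_id, gene,
    replicate, ct; comma- or tab-delimited).

    Gene symbols outside the panel (plus the reference) are rejected with a
    listing; duplicate (patient, gene, replicate) rows are an error.
    """
    df = _read_delimited(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table is missing column(s): {missing}")
    if not pd.api.types.is_numeric_dtype(df["ct"]):
        bad = df.loc[pd.to_numeric(df["ct"], errors="coerce").isna(), "ct"]
        raise ValueError(f"non-numeric ct values, e.g. {bad.head(3).tolist()}")
    allowed = set(panel) | {REFERENCE_GENE}
    unknown = sorted(set(df["gene"]) - allowed)
    if unknown:
        raise ValueError(f"unknown genes in Ct table: {unknown}")
    dup = df.duplicated(subset=["patient_id", "gene", "replicate"])
    if dup.any():
        rows = df.loc[dup, ["patient_id", "gene", "replicate"]]
        raise ValueError(
            f"duplicate (patient, gene, replicate) rows: "
            f"{[tuple(r) for r in rows.head(5).itertuples(index=False)]}"
        )
    return df[list(CT_COLUMNS)]


def read_labels(path) -> pd.DataFrame:
    """Read the label sidecar table (patient_id, label; optional psa,
    gleason, stage, core_fraction), validating the label vocabulary."""
    df = _read_delimited(path)
    for col in ("patient_id", "label"):
        if col not in df.columns:
            raise ValueError(f"label table is missing column(s): ['{col}']")
    bad = sorted(set(df["label"].dropna()) - VALID_LABELS)
    if bad:
        raise ValueError(
            f"unknown label token(s) {bad}; allowed: {sorted(VALID_LABELS)}"
        )
    optional = [c for c in ("psa", "gleason", "stage", "core_fraction")
                if c in df.columns]
    out = df[["patient_id", "label"] + optional].set_index("patient_id")
    if out.index.duplicated().any():
        raise ValueError("duplicate patient_id rows in label table")
    return out


def _parse_gleason(gleason) -> tuple[int, int | None]:
    """Total score and, when given as 'a+b', the primary pattern."""
    if isinstance(gleason, str):
        m = re.fullmatch(r"\s*(\d)\s*\+\s*(\d)\s*", gleason)
        if m:
            a, b = int(m.group(1)), int(m.group(2))
            return a + b, a
        gleason = gleason.strip()
    total = int(gleason)
    if not 2 <= total <= 10:
        raise ValueError(f"implausible Gleason score {gleason!r}")
    return total, None


def derive_risk_label(
    gleason=None, stage=None, psa=None, core_fraction=None
) -> str:
    """Binarize clinical criteria into higher_risk / lower_risk.

    higher_risk iff any of: Gleason total > 7; Gleason 4+3; cancer stage
    >= T3; PSA > 20 ng/ml (strict); more than half the biopsy core with
    cancer. Missing fields are non-qualifying (logged); if all fields are
    absent there is nothing to decide and an error is raised.
    """
    fields = dict(gleason=gleason, stage=stage, psa=psa, core_fraction=core_fraction)
    present = {k: v for k, v in fields.items() if v is not None and v == v}
    if not present:
        raise ValueError("cannot derive a risk label: all criteria fields absent")
    absent = sorted(set(fields) - set(present))
    if absent:
        logger.warning("risk criteria missing (treated as non-qualifying): %s", absent)

    if "gleason" in present:
        total, primary = _parse_gleason(present["gleason"])
        if total > 7 or (total == 7 and primary == 4):
            return HIGHER_RISK
    if "stage" in present:
        m = re.match(r"\s*T\s*(\d)", str(present["stage"]), flags=re.IGNORECASE)
        if m and int(m.group(1)) >= 3:
            return HIGHER_RISK
    if "psa" in present and float(present["psa"]) > 20.0:
        return HIGHER_RISK
    if "core_fraction" in present and float(present["core_fraction"]) > 0.5:
        return HIGHER_RISK
    return LOWER_RISK


def select_subgroup(meta: pd.DataFrame, subgroup: str | None) -> pd.Series:
    """Boolean mask implementing the report subgroup selections.

    ``gleason67`` keeps Gleason totals 6 and 7; ``gleason7`` keeps total 7
    only (the 3+4 vs 4+3 contrast). Requires a ``gleason`` column.
    """
    if subgroup is None:
        return pd.Series(True, index=meta.index)
    if "gleason" not in meta.columns:
        raise ValueError(f"subgroup {subgroup!r} requires a gleason column")
    totals = meta["gleason"].map(
        lambda g: None if pd.isna(g) else _parse_gleason(g)[0]
    )
    if subgroup == "gleason67":
        return totals.isin([6, 7])
    if subgroup == "gleason7":
        return totals == 7
    raise ValueError(f"unknown subgroup {subgroup!r}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either (``ct_path``, ``labels_path``) or a
    ``sim`` cohort configuration. The Gleason-7-split task is expressed by
    relabelling upstream; here the task is always a two-label contrast.
    """

    ct_path: str | None = None
    labels_path: str | None = None
    sim: SimConfig | None = None
    panel: GenePanel = PANEL14
    task: str = "stratification"
    prior_mode: str = "proportional"
    shrinkage: float = 0.1
    protocol: str = "resubstitution"  # or "kfold"
    k: int = 5
    scale: float = 1000
    subgroup: str | None = None
    psa_threshold: float | None = None
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        from_files = self.ct_path is not None or self.labels_path is not None
        if from_files == (self.sim is not None):
            raise ValueError(
                "exactly one input source required: ct/labels paths or sim config"
            )
        if from_files and (self.ct_path is None or self.labels_path is None):
            raise ValueError("both ct_path and labels_path are required")
        if self.protocol not in ("resubstitution", "kfold"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")
        if self.task not in ("stratification", "diagnosis"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.scale not in (1, 1000):
            raise ValueError("scale must be 1 or 1000")


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full analysis run; returns the in-memory report.

    Report keys: ``profiles`` (CtS + metadata), ``model`` (PanelModel),
    ``scores``, ``confusion``, ``roc``, ``gene_tests``, ``performance``
    (rendered table) and, under kfold, ``folds``. When ``config.outdir``
    is set every table is also written as delimited text.
    """
    config.validate()
    task_classes = (
        (HIGHER_RISK, LOWER_RISK)
        if config.task == "stratification"
        else (CANCER, BENIGN)
    )
    positive = task_classes[0]

    with _stage("input"):
        if config.sim is not None:
            truth = simulate_profiles(config.sim)
            raw = profiles_to_raw_ct(truth, config.sim)
            meta = truth[["label"]]
        else:
            raw = read_ct_table(config.ct_path, config.panel)
            meta = read_labels(config.labels_path)

    with _stage("normalize"):
        cts = normalize_table(raw, config.panel, scale=config.scale)
        profiles = cts.join(meta, how="inner")
        if len(profiles) < len(cts):
            logger.warning(
                "%d patients lack labels and were dropped", len(cts) - len(profiles)
            )

    with _stage("subgroup"):
        mask = select_subgroup(profiles, config.subgroup)
        profiles = profiles.loc[mask]

    fit = fit_stratifier if config.task == "stratification" else fit_diagnoser

    with _stage("fit"):
        clf = fit(profiles, config.panel, config.prior_mode, config.shrinkage)
        model = clf.to_panel_model(config.panel)

    eligible = profiles["label"].isin(task_classes)
    train = profiles.loc[eligible]
    folds = []
    with _stage("score"):
        if config.protocol == "resubstitution":
            scores = score_profiles(model, train)
        else:
            from sklearn.model_selection import StratifiedKFold

            splitter = StratifiedKFold(
                n_splits=config.k, shuffle=True, random_state=config.seed
            )
            parts = []
            y = train["label"].to_numpy()
            for i, (tr, te) in enumerate(splitter.split(np.zeros(len(train)), y)):
                fold_clf = fit(
                    train.iloc[tr], config.panel, config.prior_mode, config.shrinkage
                )
                part = score_profiles(fold_clf, train.iloc[te], config.panel)
                part["fold"] = i
                parts.append(part)
                folds.append(
                    confusion(part["call"], train.iloc[te]["label"], positive)
                )
            scores = pd.concat(parts).loc[train.index]

    with _stage("evaluate"):
        cm = confusion(scores["call"], train["label"], positive)
        roc_res = roc(scores["d_score"], train["label"], positive)
        tests = gene_ttest_table(train, list(config.panel), task_classes)
        summaries = {config.panel.name: cm}
        psa_roc = None
        if config.psa_threshold is not None or (
            "psa" in train.columns and train["psa"].notna().all()
        ):
            if "psa" not in train.columns:
                raise ValueError("psa_threshold set but no psa column present")
            with_psa = train["psa"].notna()
            psa_roc = roc(
                train.loc[with_psa, "psa"], train.loc[with_psa, "label"], positive
            )
            if config.psa_threshold is not None:
                psa_calls = np.where(
                    train.loc[with_psa, "psa"] > config.psa_threshold,
                    positive,
                    task_classes[1],
                )
                summaries["PSA"] = confusion(
                    psa_calls, train.loc[with_psa, "label"], positive
                )
        perf = performance_table(summaries)

    report = {
        "profiles": profiles,
        "model": model,
        "scores": scores,
        "confusion": cm,
        "roc": roc_res,
        "psa_roc": psa_roc,
        "gene_tests": tests,
        "performance": perf,
        "folds": folds,
    }

    if config.outdir is not None:
        _write_outputs(config, report)
    return report


def _write_outputs(config: RunConfig, report: dict) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report["profiles"].to_csv(out / "profiles.csv")
    report["model"].save(out / "model.json")
    report["scores"].to_csv(out / "scores.csv")
    report["performance"].to_csv(out / "performance.csv")
    (out / "performance.txt").write_text(
        report["performance"].to_string() + "\n"
    )
    report["roc"].to_frame().to_csv(out / "roc.csv", index=False)
    report["gene_tests"].to_csv(out / "gene_tests.csv")
    run_info = {
        "version": __version__,
        "seed": config.seed,
        "panel": config.panel.name,
        "task": config.task,
        "protocol": config.protocol,
        "k": config.k if config.protocol == "kfold" else None,
        "prior_mode": config.prior_mode,
        "shrinkage": config.shrinkage,
        "scale": config.scale,
        "subgroup": config.subgroup,
        "n_samples": int(len(report["scores"])),
        "auc": report["roc"].auc,
        "auc_ci": list(report["roc"].auc_ci),
    }
    with open(out / "run.json", "w") as fh:
        json.dump(run_info, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info(
        "run complete: task=%s panel=%s protocol=%s seed=%d version=%s",
        config.task, config.panel.name, config.protocol, config.seed, __version__,
    )
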