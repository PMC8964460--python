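"""Glue between file interfaces and the library: batch feature extraction,
TSV feature tables, and sequential (lifelong) training over a task order.

Each task in the stream learns one class.  Because earlier tasks' data is
assumed unavailable, every task builds its binary training set from the
current feature file only: members of the task's class are the positives and
all other rows of that file are its negatives.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from memdsn.dsn import DSNConfig, DSNModel, TrainReport, init_model, train_task
from memdsn.errors import MemdsnError
from memdsn.features import FeatureConfig, extract_all, feature_names
from memdsn.pssm_io import PSSM, parse_ascii_pssm

logger = logging.getLogger(__name__)


def extract_dir(pssm_dir: str | Path, cfg: FeatureConfig | None = None):
    """Parse every ``*.pssm`` file in a directory and extract features.

    Unparseable files are skipped with a warning (real profile directories
    are messy); returns ``(ids, X)`` in sorted-filename order.
    """
    cfg = cfg or FeatureConfig()
    ids, rows = [], []
    for path in sorted(Path(pssm_dir).glob("*.pssm")):
        try:
            pssm = parse_ascii_pssm(path)
            rows.append(extract_all(pssm, cfg).values)
            ids.append(pssm.id)
        except (MemdsnError, OSError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
    if not rows:
        return [], np.empty((0, cfg.total_length))
    return ids, np.vstack(rows)


def extract_batch(pssms: list[PSSM], cfg: FeatureConfig | None = None) -> np.ndarray:
    cfg = cfg or FeatureConfig()
    return np.vstack([extract_all(p, cfg).values for p in pssms])


def features_to_tsv(ids: list[str], X: np.ndarray, path: str | Path,
                    cfg: FeatureConfig | None = None) -> None:
    df = pd.DataFrame(X, columns=feature_names(cfg))
    df.insert(0, "protein_id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_features_tsv(path: str | Path):
    df = pd.read_csv(path, sep="\t")
    ids = df["protein_id"].astype(str).tolist()
    X = df.drop(columns="protein_id").to_numpy(dtype=float)
    return ids, X


def stream_to_arrays(tasks, cfg: FeatureConfig | None = None):
    """Flatten a labelled task stream into (ids, X, y) arrays."""
    pssms = [p for _, group in tasks for p in group]
    X = extract_batch(pssms, cfg)
    y = np.array([p.label for p in pssms])
    return [p.id for p in pssms], X, y


def train_stream(
    X: np.ndarray,
    y: np.ndarray,
    task_order: list[int],
    dsn_cfg: DSNConfig | None = None,
    model: DSNModel | None = None,
) -> tuple[DSNModel, list[TrainReport]]:
    """Sequentially learn the classes in ``task_order`` as one-vs-rest tasks.

    Task t sees only the rows of the current table: positives are rows
    labelled t, negatives all other rows.
    """
    dsn_cfg = dsn_cfg or DSNConfig()
    present = set(np.unique(y).tolist())
    missing = [c for c in task_order if c not in present]
    if missing:
        raise ValueError(f"task_order lists classes with no data: {missing}")
    if model is None:
        model = init_model(dsn_cfg, X.shape[1])
    reports = []
    for cls in task_order:
        y_bin = (y == cls).astype(float)
        model, report = train_task(model, X, y_bin, dsn_cfg)
        reports.append(report)
        logger.info("task %d (class %d): %s", report.task_index, cls, report.to_json())
    return model, reports
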