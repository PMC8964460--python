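"""Synthetic labelled PSSMs with controllable class separation.

Real profiles require an iterative PSI-BLAST search against a large sequence
database; this generator instead emulates their two properties that the
downstream pipeline is sensitive to: integer log-odds matrices whose column
means carry a class signal, and a heavy-tailed (log-normal) distribution of
sequence lengths.  Each class c has a 20-dimensional template equal to a
shared random base plus ``separation`` added to coordinate c, so any two
templates are exactly ``separation * sqrt(2)`` apart; rows are the template
plus independent Gaussian noise, rounded to integers like ASCII PSSM
log-odds.  Positional motifs are deliberately not modelled: every extractor
in the pipeline is sensitive to column statistics, which keeps oracle
computations tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from memdsn.pssm_io import PSSM, write_ascii_pssm, write_labels


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic task stream.

    Defaults give the 8-class benchmark stream: 100 proteins per class,
    template separation 8 against unit row noise, log-normal lengths
    (log-mean 5.5, log-sd 0.8 — median ~245 residues with a heavy right
    tail) clipped to at least 16 so a 4-level wavelet cascade is defined.
    """

    n_classes: int = 8
    n_per_class: int = 100
    separation: float = 8.0
    noise_sd: float = 1.0
    length_log_mean: float = 5.5
    length_log_sd: float = 0.8
    min_length: int = 16
    seed: int = 0
    #: seed for the class templates; defaults to ``seed``.  Give a train and
    #: a test spec the same template_seed but different seeds to draw two
    #: independent samples from the same class population.
    template_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.separation < 0 or self.noise_sd < 0:
            raise ValueError("separation and noise_sd must be non-negative")
        if self.min_length < 16:
            raise ValueError("min_length must be >= 16 (4-level wavelet cascade)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def make_class_templates(n_classes: int, separation: float, seed: int) -> list[np.ndarray]:
    """Class mean-score templates: a shared random base plus a one-hot offset
    of height ``separation`` on coordinate c for class c, so every pair of
    templates is ``separation * sqrt(2)`` apart in Euclidean distance."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_classes > 20:
        raise ValueError("at most 20 classes (one offset coordinate per class)")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 2.0, size=20)
    templates = []
    for c in range(n_classes):
        t = base.copy()
        t[c] += separation
        templates.append(t)
    return templates


def sample_pssm(
    template: np.ndarray,
    length: int,
    noise_sd: float,
    seed: int,
    id: str = "synthetic",
    label: int | None = None,
) -> PSSM:
    """One synthetic profile: each row is the template plus independent
    Gaussian noise (sd ``noise_sd``), rounded to integer log-odds."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.asarray(template, dtype=float) + rng.normal(0.0, noise_sd, size=(length, 20))
    scores = np.rint(rows).astype(np.int64)
    return PSSM(id=id, scores=scores, label=label)


def generate_task_stream(spec: SyntheticSpec) -> list[tuple[int, list[PSSM]]]:
    """The lifelong task stream: one task per class in class order 1..n_classes,
    task t holding ``n_per_class`` labelled profiles of class t with log-normal
    lengths clipped to ``min_length``.  Fully reproducible from ``spec.seed``."""
    tseed = spec.seed if spec.template_seed is None else spec.template_seed
    templates = make_class_templates(spec.n_classes, spec.separation, tseed)
    rng = np.random.default_rng(spec.seed)
    tasks = []
    for c in range(1, spec.n_classes + 1):
        pssms = []
        for i in range(spec.n_per_class):
            length = max(spec.min_length, int(np.rint(rng.lognormal(spec.length_log_mean, spec.length_log_sd))))
            sample_seed = int(rng.integers(0, 2**31 - 1))
            pssms.append(
                sample_pssm(
                    templates[c - 1], length, spec.noise_sd, sample_seed,
                    id=f"c{c}_s{i}", label=c,
                )
            )
        tasks.append((c, pssms))
    return tasks


def write_stream(tasks: list[tuple[int, list[PSSM]]], out_dir: str | Path) -> None:
    """Write a task stream as ASCII PSSM files plus a ``labels.tsv``, so
    synthetic data flows through the same file interfaces as real data."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = {}
    for cls, pssms in tasks:
        for p in pssms:
            write_ascii_pssm(p, out_dir / f"{p.id}.pssm")
            labels[p.id] = cls
    write_labels(labels, out_dir / "labels.tsv")
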