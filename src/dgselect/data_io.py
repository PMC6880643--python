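"""Expression-matrix I/O, synthetic data generation, and result reports.

The canonical in-memory orientation is samples × attributes. Microarray
exports are commonly shipped the other way round (probes in rows), so the
loader takes an orientation flag and transposes on load. Only plain
delimited text (comma or tab, sniffed) is supported; users export matrices
from their repositories themselves.

The synthetic generator plants a small set of class-informative attributes
(mean-shifted between two classes) among pure-noise attributes — the shape
of a typical few-samples / many-probes microarray problem.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .evolution import RunResult

__all__ = [
    "ExpressionDataset",
    "SyntheticSpec",
    "read_dataset",
    "write_dataset",
    "synthesize",
    "write_result",
]

logger = logging.getLogger(__name__)

#: attributes with a larger fraction of missing values are rejected
MAX_MISSING_FRACTION = 0.05


@dataclass(frozen=True)
class ExpressionDataset:
    """A numeric expression matrix with sample/attribute IDs and class labels."""

    X: np.ndarray  # samples x attributes, float, no missing values
    sample_ids: tuple[str, ...]
    attribute_ids: tuple[str, ...]
    labels: np.ndarray  # one class label per sample

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x attributes)")
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("one sample ID per row required")
        if len(self.attribute_ids) != self.X.shape[1]:
            raise ValueError("one attribute ID per column required")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label per sample required")
        if len(set(self.attribute_ids)) != len(self.attribute_ids):
            raise ValueError("attribute IDs must be unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.X.shape[1]


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    counts = {sep: header.count(sep) for sep in (",", "\t", ";")}
    sep = max(counts, key=counts.get)
    if counts[sep] == 0:
        raise ValueError(f"could not sniff a delimiter in {path}")
    return sep


def _read_table(path) -> pd.DataFrame:
    # round_trip parsing so written float64 values are recovered exactly
    return pd.read_csv(
        path,
        sep=_sniff_delimiter(path),
        index_col=0,
        float_precision="round_trip",
    )


def read_dataset(
    path,
    orientation: str = "samples_in_rows",
    label_col: str | None = None,
    label_file=None,
) -> ExpressionDataset:
    """Load a delimited expression matrix plus class labels.

    ``orientation`` is ``"samples_in_rows"`` or ``"attributes_in_rows"``
    (series-matrix style; transposed on load). Labels come either from a
    matrix column named ``label_col`` or from a separate two-column file
    (sample ID, class). Isolated missing values (at most 5% per attribute)
    are mean-imputed with a logged count; anything worse is rejected.
    """
    if orientation not in ("samples_in_rows", "attributes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if (label_col is None) == (label_file is None):
        raise ValueError("provide exactly one of label_col or label_file")

    frame = _read_table(path)
    if orientation == "attributes_in_rows":
        frame = frame.T

    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dupes}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate attribute IDs: {dupes}")

    sample_ids = tuple(str(s) for s in frame.index)

    if label_col is not None:
        if label_col not in frame.columns:
            raise ValueError(f"label column {label_col!r} not found")
        labels = frame[label_col].astype(str).to_numpy()
        frame = frame.drop(columns=[label_col])
    else:
        lab = pd.read_csv(label_file, sep=None, engine="python", header=None)
        if lab.shape[1] != 2:
            raise ValueError("label file must have two columns: sample ID, class")
        mapping = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str)))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"label file is missing sample IDs: {missing}")
        labels = np.array([mapping[s] for s in sample_ids])

    # to_numeric only flags problems; the actual conversion below uses exact
    # per-element parsing so written values are recovered bit-for-bit
    probed = frame.apply(pd.to_numeric, errors="coerce")
    bad = probed.isna() & frame.notna()
    if bad.to_numpy().any():
        cells = [
            f"({frame.index[i]}, {frame.columns[j]})"
            for i, j in zip(*np.nonzero(bad.to_numpy()))
        ][:5]
        raise ValueError(f"non-numeric cells at {', '.join(cells)}")

    missing_frac = probed.isna().mean(axis=0)
    too_sparse = missing_frac[missing_frac > MAX_MISSING_FRACTION]
    if not too_sparse.empty:
        raise ValueError(
            f"attributes exceed {MAX_MISSING_FRACTION:.0%} missing values: "
            f"{too_sparse.index.tolist()}"
        )
    numeric = frame.astype(float)
    n_imputed = int(numeric.isna().to_numpy().sum())
    if n_imputed:
        logger.info("mean-imputing %d isolated missing values", n_imputed)
        numeric = numeric.fillna(numeric.mean(axis=0))

    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class")

    return ExpressionDataset(
        X=numeric.to_numpy(dtype=float),
        sample_ids=sample_ids,
        attribute_ids=tuple(str(a) for a in numeric.columns),
        labels=labels,
    )


def write_dataset(
    dataset: ExpressionDataset,
    path,
    orientation: str = "samples_in_rows",
    label_col: str = "class",
) -> None:
    """Write a dataset as CSV with a label column (inverse of the loader)."""
    frame = pd.DataFrame(
        dataset.X, index=list(dataset.sample_ids), columns=list(dataset.attribute_ids)
    )
    frame[label_col] = dataset.labels
    if orientation == "attributes_in_rows":
        frame = frame.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    # %.17g guarantees float64 values survive the text round-trip exactly
    frame.to_csv(path, float_format="%.17g")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-signal generator.

    Defaults emulate a small two-class expression study: 60 samples, 500
    continuous attributes of which 5 carry a 2-standard-deviation class-mean
    shift, balanced classes.
    """

    n_samples: int = 60
    n_attributes: int = 500
    n_informative: int = 5
    effect_size: float = 2.0  # class-mean shift in units of noise SD
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if not 0 <= self.n_informative <= self.n_attributes:
            raise ValueError("n_informative must lie in [0, n_attributes]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")


def synthesize(spec: SyntheticSpec) -> tuple[ExpressionDataset, tuple[str, ...]]:
    """Generate a two-class dataset with planted informative attributes.

    Background attributes are Normal(0, noise_sd²) independent of class;
    informative attributes additionally gain ``effect_size * noise_sd`` in
    the "case" class. Labels are drawn i.i.d. with probability
    ``class_balance`` of "case" (re-drawn until both classes have at least
    two members so the dataset is always usable). Deterministic given the
    spec's seed. Returns the dataset and the planted attribute IDs.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_attributes - 1))
    attribute_ids = tuple(f"a{i:0{width}d}" for i in range(spec.n_attributes))
    sample_ids = tuple(f"s{i:03d}" for i in range(spec.n_samples))

    while True:
        is_case = rng.random(spec.n_samples) < spec.class_balance
        if 2 <= is_case.sum() <= spec.n_samples - 2:
            break
    labels = np.where(is_case, "case", "control")

    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_attributes))
    informative = rng.choice(
        spec.n_attributes, size=spec.n_informative, replace=False
    )
    informative = np.sort(informative)
    X[np.ix_(is_case, informative)] += spec.effect_size * spec.noise_sd

    dataset = ExpressionDataset(
        X=X, sample_ids=sample_ids, attribute_ids=attribute_ids, labels=labels
    )
    truth = tuple(attribute_ids[i] for i in informative)
    return dataset, truth


def write_result(
    result: "RunResult",
    out_dir,
    config=None,
    extras: dict | None = None,
) -> dict[str, Path]:
    """Write the three report files for a completed run.

    ``selected.tsv`` (rank, attribute ID, weight), ``generations.tsv``
    (per-generation log) and ``summary.yaml`` (config echo, best scores,
    termination reason; timestamp only in a comment header so re-runs with
    the same seed are byte-identical below it).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    selected_path = out / "selected.tsv"
    with selected_path.open("w") as fh:
        fh.write("rank\tattribute_id\tweight\n")
        for rank, attr in enumerate(result.selected, start=1):
            fh.write(f"{rank}\t{attr}\t{result.weights.weight(attr):.6g}\n")

    log_path = out / "generations.tsv"
    with log_path.open("w") as fh:
        fh.write("generation\tT\th\tbest_f\tbest_AC\tbest_s\n")
        for entry in result.log:
            fh.write(
                f"{entry.generation}\t{entry.T}\t{entry.h}\t"
                f"{entry.best_f:.6g}\t{entry.best_AC:.6g}\t{entry.best_s}\n"
            )

    summary = {
        "seed": result.seed,
        "selected": list(result.selected),
        "selected_count": len(result.selected),
        "best_fitness": float(result.best.f),
        "best_accuracy": float(result.best.AC),
        "best_subset_size": int(result.best.s),
        "best_chromosome": result.best_chromosome,
        "best_ever_fitness": float(result.best_ever.f),
        "generations": result.generations,
        "termination": result.termination,
    }
    if config is not None:
        summary["config"] = {
            k: v
            for k, v in vars(config).items()
            if isinstance(v, (int, float, str, bool))
        }
    if extras:
        summary.update(extras)
    summary_path = out / "summary.yaml"
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with summary_path.open("w") as fh:
        fh.write(f"# written: {stamp}\n")
        yaml.safe_dump(summary, fh, sort_keys=True)

    return {
        "selected": selected_path,
        "generations": log_path,
        "summary": summary_path,
    }
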