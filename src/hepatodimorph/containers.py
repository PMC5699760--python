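"""Core in-memory containers for the expression analysis pipeline.

Expression values are log10 ratios of a sample channel against a common
reference channel, so a difference of group means on this scale is the
log10 of a (geometric-mean) fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SEXES = ("M", "F")
#: chromosome vocabulary: autosomes 1..22, the sex chromosomes, or unknown
VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "unknown")


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log10(sample/reference) expression ratios."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene_id")
        _check_unique(self.sample_ids, "sample_id")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Row-subset in the given order; unknown ids raise."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise ValidationError(f"gene_id not in matrix: {exc.args[0]!r}") from exc
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows])


@dataclass
class SampleTable:
    """Sample sheet mapping sample_id -> sex label (M or F)."""

    sample_ids: list[str]
    sex: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.sex = [str(s) for s in self.sex]
        if len(self.sample_ids) != len(self.sex):
            raise ValidationError("sample_ids and sex differ in length")
        _check_unique(self.sample_ids, "sample_id")
        for sid, sx in zip(self.sample_ids, self.sex):
            if sx not in VALID_SEXES:
                raise ValidationError(
                    f"sample {sid!r}: sex must be one of {VALID_SEXES}, got {sx!r}"
                )

    def sex_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.sex))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "sex": self.sex})


@dataclass
class GeneTable:
    """Per-gene annotation: symbol, chromosome and DMET membership flag."""

    gene_ids: list[str]
    symbols: list[str]
    chromosomes: list[str]
    is_dmet: list[bool]
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        n = len(self.gene_ids)
        if not (len(self.symbols) == len(self.chromosomes) == len(self.is_dmet) == n):
            raise ValidationError("gene table columns differ in length")
        _check_unique(self.gene_ids, "gene_id")
        for g, c in zip(self.gene_ids, self.chromosomes):
            if c not in VALID_CHROMOSOMES:
                raise ValidationError(
                    f"gene {g!r}: chromosome must be 1..22, X, Y or unknown, got {c!r}"
                )
        self.is_dmet = [bool(v) for v in self.is_dmet]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "symbol": self.symbols,
                "chromosome": self.chromosomes,
                "is_dmet": self.is_dmet,
            }
        )
        if self.extra is not None:
            frame = pd.concat([frame, self.extra.reset_index(drop=True)], axis=1)
        return frame


def split_by_sex(
    matrix: ExpressionMatrix, samples: SampleTable
) -> tuple[np.ndarray, np.ndarray]:
    """Return boolean column masks (female, male) for the matrix.

    Every matrix sample must appear in the sample sheet and both sexes must
    be represented by at least two samples.
    """
    sex_of = samples.sex_of()
    try:
        sex = np.array([sex_of[s] for s in matrix.sample_ids])
    except KeyError as exc:
        raise ValidationError(f"sample {exc.args[0]!r} missing from sample sheet") from exc
    female = sex == "F"
    male = sex == "M"
    if female.sum() < 2 or male.sum() < 2:
        raise ValidationError(
            f"need >=2 samples of each sex, got {int(female.sum())} F / {int(male.sum())} M"
        )
    return female, male
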