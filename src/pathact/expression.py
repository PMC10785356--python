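"""Expression-matrix I/O, imputation, and per-gene statistics.

The central container is :class:`ExpressionDataset`: a genes x samples matrix of
continuous expression values with a binary phenotype label (``normal`` /
``tumour``) per sample.  Every activity-inference scheme in this package
consumes either the row-standardised form (:class:`ZMatrix`) or the per-gene
two-sample statistics (:class:`GeneStatistics`) computed here.

Conventions
-----------
* The t statistic is pooled-variance, two-sample, oriented tumour minus
  normal: positive t means up-regulated in tumour.
* Standard deviations use the n-1 denominator throughout.
* ``sign(0)`` maps to +1 so signed products stay defined for t = 0 genes.
* Constant gene rows z-score to all-zero rows and are flagged rather than
  raising, so downstream sums stay finite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "ExpressionDataset",
    "ZMatrix",
    "GeneStatistics",
    "parse_expression",
    "read_gct",
    "read_expression_tsv",
    "read_cls",
    "read_label_tsv",
    "write_gct",
    "write_cls",
    "impute_missing_mean",
    "zscore_rows",
    "gene_statistics",
    "gene_entropy",
    "entropy_rows",
    "pooled_tscores",
]

NORMAL = "normal"
TUMOUR = "tumour"


class FormatError(ValueError):
    """Malformed input stream (wrong field counts, bad headers...)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a dataset contract."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with binary phenotype labels.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene ids, columns are sample ids.
    labels
        Series over the same samples with values in ``{"normal", "tumour"}``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if list(self.labels.index) != list(self.values.columns):
            self.labels = self.labels.reindex(self.values.columns)
            if self.labels.isna().any():
                raise ValidationError("labels do not cover all samples")
        classes = set(self.labels.unique())
        if classes - {NORMAL, TUMOUR}:
            raise ValidationError(f"unexpected labels {classes - {NORMAL, TUMOUR}}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_mask(self) -> np.ndarray:
        """Boolean vector per sample, True for tumour."""
        return (self.labels == TUMOUR).to_numpy()

    def require_two_classes(self, min_per_class: int = 2) -> None:
        counts = self.labels.value_counts()
        if len(counts) != 2 or (counts < min_per_class).any():
            raise ValidationError(
                "need two classes with >= "
                f"{min_per_class} samples each, got {counts.to_dict()}"
            )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values[list(sample_ids)].copy(), self.labels.loc[list(sample_ids)].copy()
        )


@dataclass
class ZMatrix:
    """Row-standardised expression: each gene row has mean 0, sd 1 (n-1).

    Constant source rows become all-zero rows and are listed in
    ``constant_genes``.
    """

    values: pd.DataFrame
    constant_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneStatistics:
    """Per-gene two-sample statistics, indexed like the source dataset.

    Fields are aligned pandas Series: ``tscore`` (pooled-variance t, tumour
    minus normal), ``pvalue`` (two-tailed), ``sign`` (+1/-1, sign(0) -> +1),
    ``pbc`` (point-biserial correlation with the 0/1 tumour indicator),
    ``pct`` (pbc + t, both signed), and ``entropy`` (Shannon entropy of the per-gene
    expression histogram, bits).  ``zero_variance_genes`` lists genes whose
    pooled variance was zero (t forced to 0, p to 1).
    """

    tscore: pd.Series
    pvalue: pd.Series
    sign: pd.Series
    pbc: pd.Series
    pct: pd.Series
    entropy: pd.Series
    zero_variance_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parsing


def _clean_lines(stream) -> list[str]:
    if isinstance(stream, (str, bytes)):
        raise TypeError("pass an open text stream or path-like, not raw content")
    text = stream.read()
    lines = [ln.rstrip("\r") for ln in text.split("\n")]
    while lines and not lines[-1].strip():
        lines.pop()
    return lines


def read_gct(stream) -> pd.DataFrame:
    """Read a GCT v1.2 matrix (two header lines, then Name/Description/samples)."""
    lines = _clean_lines(stream)
    if len(lines) < 3 or not lines[0].startswith("#1.2"):
        raise FormatError("not a GCT v1.2 stream (missing '#1.2' header)")
    try:
        n_rows, n_cols = (int(tok) for tok in lines[1].split()[:2])
    except (ValueError, IndexError) as exc:
        raise FormatError("bad GCT dimension line") from exc
    body = "\n".join(lines[2:])
    df = pd.read_csv(io.StringIO(body), sep="\t")
    if df.shape[1] < 3:
        raise FormatError("GCT needs Name, Description and >= 1 sample column")
    df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    if df.shape != (n_rows, n_cols):
        raise FormatError(
            f"GCT header declares {n_rows}x{n_cols}, body is {df.shape[0]}x{df.shape[1]}"
        )
    return df.astype(float)


def read_expression_tsv(stream) -> pd.DataFrame:
    """Read a headered TSV with gene ids in the first column."""
    lines = _clean_lines(stream)
    if not lines:
        raise FormatError("empty expression stream")
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    return df.astype(float)


def read_cls(stream) -> list[str]:
    """Read GenePattern CLS labels, returning normal/tumour per sample.

    Line 1 is ``n_samples n_classes 1``; line 2 optionally names the classes
    (``# name0 name1``); line 3 holds one token per sample (indices or class
    names).  With numeric tokens, 0 maps to normal and 1 to tumour.
    """
    lines = [ln for ln in _clean_lines(stream) if ln.strip()]
    if len(lines) < 2:
        raise FormatError("CLS stream needs a header and a label line")
    head = lines[0].split()
    try:
        n_samples, n_classes = int(head[0]), int(head[1])
    except (ValueError, IndexError) as exc:
        raise FormatError("bad CLS header line") from exc
    if n_classes != 2:
        raise ValidationError(f"need exactly 2 classes, CLS declares {n_classes}")
    names: list[str] | None = None
    body_idx = 1
    if lines[1].lstrip().startswith("#"):
        names = lines[1].lstrip("# ").split()
        body_idx = 2
    if body_idx >= len(lines):
        raise FormatError("CLS stream missing the label line")
    tokens = lines[body_idx].split()
    if len(tokens) != n_samples:
        raise FormatError(f"CLS declares {n_samples} samples, found {len(tokens)} labels")
    distinct = list(dict.fromkeys(tokens))
    if len(distinct) != 2:
        raise ValidationError(f"need exactly 2 label values, found {len(distinct)}")
    mapping: dict[str, str] = {}
    lowered = {t.lower() for t in tokens}
    if lowered <= {"0", "1"}:
        mapping = {"0": NORMAL, "1": TUMOUR}
    elif names is not None and set(tokens) <= {"0", "1"} | set(names):
        mapping = {"0": NORMAL, "1": TUMOUR, names[0]: NORMAL, names[1]: TUMOUR}
    else:
        # class-name tokens: first-seen class is normal unless names say otherwise
        tumour_like = [t for t in distinct if "tumo" in t.lower() or "cancer" in t.lower()]
        if len(tumour_like) == 1:
            other = next(t for t in distinct if t != tumour_like[0])
            mapping = {other: NORMAL, tumour_like[0]: TUMOUR}
        else:
            mapping = {distinct[0]: NORMAL, distinct[1]: TUMOUR}
    return [mapping[t] for t in tokens]


def read_label_tsv(stream) -> pd.Series:
    """Read a two-column sample/label TSV (header optional)."""
    lines = [ln for ln in _clean_lines(stream) if ln.strip()]
    if not lines:
        raise FormatError("empty label stream")
    rows = [ln.split("\t") for ln in lines]
    if any(len(r) != 2 for r in rows):
        raise FormatError("label TSV must have exactly two columns")
    if rows[0][1].lower() in {"label", "class", "phenotype"}:
        rows = rows[1:]
    labels = pd.Series(
        {sid: lab.strip().lower() for sid, lab in rows}, name="label"
    )
    distinct = sorted(labels.unique())
    if len(distinct) != 2:
        raise ValidationError(f"need exactly 2 label values, found {len(distinct)}")
    if set(distinct) != {NORMAL, TUMOUR}:
        mapping = {"0": NORMAL, "1": TUMOUR}
        if set(distinct) <= set(mapping):
            labels = labels.map(mapping)
        else:
            labels = labels.map({distinct[0]: NORMAL, distinct[1]: TUMOUR})
    return labels


def parse_expression(matrix_source, label_source) -> ExpressionDataset:
    """Parse a matrix stream (GCT or headered TSV) plus a label stream.

    Duplicate gene rows are collapsed by their mean.  The label stream may be
    CLS (positional, aligned to sample order) or a two-column TSV keyed by
    sample id.
    """
    text = matrix_source.read()
    if text.lstrip().startswith("#1.2"):
        df = read_gct(io.StringIO(text))
    else:
        df = read_expression_tsv(io.StringIO(text))
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()

    label_text = label_source.read()
    stripped = label_text.lstrip()
    first = stripped.split("\n", 1)[0] if stripped else ""
    if "\t" in first and not first.split()[0].isdigit():
        labels = read_label_tsv(io.StringIO(label_text))
        labels = labels.reindex(df.columns)
        if labels.isna().any():
            raise FormatError("label TSV does not cover every sample id")
    else:
        cls = read_cls(io.StringIO(label_text))
        if len(cls) != df.shape[1]:
            raise FormatError(
                f"matrix has {df.shape[1]} samples but labels cover {len(cls)}"
            )
        labels = pd.Series(cls, index=df.columns, name="label")
    ds = ExpressionDataset(df, labels)
    ds.require_two_classes()
    return ds


def write_gct(dataset: ExpressionDataset, stream) -> None:
    df = dataset.values
    stream.write("#1.2\n")
    stream.write(f"{df.shape[0]}\t{df.shape[1]}\n")
    out = df.copy()
    out.insert(0, "Description", "na")
    out.index.name = "Name"
    out.to_csv(stream, sep="\t")


def write_cls(dataset: ExpressionDataset, stream) -> None:
    stream.write(f"{dataset.n_samples}\t2\t1\n")
    stream.write(f"# {NORMAL} {TUMOUR}\n")
    stream.write(" ".join("1" if t else "0" for t in dataset.class_mask()) + "\n")


# ---------------------------------------------------------------------------
# transforms and statistics


def impute_missing_mean(dataset: ExpressionDataset) -> tuple[ExpressionDataset, int]:
    """Fill each missing entry with its gene-row mean over observed entries.

    Rows that are entirely missing cannot be imputed; they are dropped and
    their count returned alongside the imputed dataset.
    """
    df = dataset.values
    all_missing = df.isna().all(axis=1)
    n_dropped = int(all_missing.sum())
    df = df.loc[~all_missing]
    row_means = df.mean(axis=1)
    filled = df.T.fillna(row_means).T
    return ExpressionDataset(filled, dataset.labels.copy()), n_dropped


def zscore_rows(dataset: ExpressionDataset) -> ZMatrix:
    """Standardise each gene row to mean 0, sd 1 (n-1 denominator).

    Constant rows become all zeros and are flagged instead of raising.
    """
    if dataset.n_samples < 2:
        raise ValidationError("z-scoring needs >= 2 samples")
    x = dataset.values.to_numpy(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    sd[constant, 0] = 1.0
    z = (x - mean) / sd
    z[constant, :] = 0.0
    return ZMatrix(
        pd.DataFrame(z, index=dataset.values.index, columns=dataset.values.columns),
        constant_genes=list(dataset.values.index[constant]),
    )


def pooled_tscores(x: np.ndarray, tumour_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled-variance two-sample t (tumour - normal) with p-values.

    Rows with zero pooled variance get t = 0, p = 1.  Returns
    (t, p, zero_variance_mask).
    """
    g1 = x[:, tumour_mask]
    g0 = x[:, ~tumour_mask]
    n1, n0 = g1.shape[1], g0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValidationError("each class needs >= 2 samples for a t-test")
    m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
    ss1 = ((g1 - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((g0 - m0[:, None]) ** 2).sum(axis=1)
    dof = n1 + n0 - 2
    sp2 = (ss1 + ss0) / dof
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    zero = se == 0.0
    se_safe = np.where(zero, 1.0, se)
    t = (m1 - m0) / se_safe
    t[zero] = 0.0
    p = 2.0 * _sstats.t.sf(np.abs(t), dof)
    p[zero] = 1.0
    return t, p, zero


def gene_statistics(dataset: ExpressionDataset, entropy_bins: int | None = None) -> GeneStatistics:
    """Compute the per-gene statistics every inference method consumes.

    t and p come from the pooled-variance two-sample t-test (tumour minus
    normal, two-tailed); ``pbc`` is the Pearson correlation of the gene row
    with the 0/1 tumour indicator; ``pct = pbc + t`` (the signed sum, so a
    down-regulated gene carries a negative weight); ``entropy`` is the
    histogram entropy of the row (Sturges bins unless ``entropy_bins`` given).
    """
    dataset.require_two_classes()
    x = dataset.values.to_numpy(float)
    mask = dataset.class_mask()
    t, p, zero = pooled_tscores(x, mask)
    sign = np.where(t >= 0.0, 1.0, -1.0)

    y = mask.astype(float)
    yc = y - y.mean()
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    safe = denom > 0
    pbc = np.zeros(x.shape[0])
    pbc[safe] = (xc[safe] @ yc) / denom[safe]

    if entropy_bins is None:
        entropy_bins = int(np.ceil(np.log2(x.shape[1]) + 1))
    ent = entropy_rows(x, entropy_bins)

    idx = dataset.values.index
    return GeneStatistics(
        tscore=pd.Series(t, index=idx, name="tscore"),
        pvalue=pd.Series(p, index=idx, name="pvalue"),
        sign=pd.Series(sign, index=idx, name="sign"),
        pbc=pd.Series(pbc, index=idx, name="pbc"),
        pct=pd.Series(pbc + t, index=idx, name="pct"),
        entropy=pd.Series(ent, index=idx, name="entropy"),
        zero_variance_genes=list(idx[zero]),
    )


def entropy_rows(x: np.ndarray, bins: int) -> np.ndarray:
    """Row-wise histogram entropy (bits), vectorised over genes.

    Same estimator as :func:`gene_entropy`: equal-width bins over each row's
    [min, max]; constant rows score 0.
    """
    x = np.asarray(x, float)
    g, n = x.shape
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0.0
    span[constant, 0] = 1.0
    idx = np.minimum((x - lo) / span * bins, bins - 1).astype(np.int64)
    # one flat bincount: offset each row into its own block of bins
    flat = (np.arange(g)[:, None] * bins + idx).ravel()
    counts = np.bincount(flat, minlength=g * bins).reshape(g, bins)
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    ent = -terms.sum(axis=1)
    ent[constant] = 0.0
    return ent


def gene_entropy(values: np.ndarray, bins: int) -> float:
    """Shannon entropy (bits) of an equal-width histogram over [min, max].

    A constant vector has zero entropy; empty bins contribute nothing.  The
    result is bounded by log2(bins).
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValidationError("entropy needs >= 2 values")
    if bins < 1:
        raise ValidationError("bins must be positive")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    probs = counts[counts > 0] / values.size
    return float(-(probs * np.log2(probs)).sum())
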