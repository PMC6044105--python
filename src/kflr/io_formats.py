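"""Reading and writing DREAM4-style benchmark files.

Three plain-text tab-delimited formats are supported:

* time-series expression: a header line ``Time<TAB>G1<TAB>G2...`` followed by
  blocks of rows, one block per replicate series.  Blocks are separated by a
  blank line; if blank lines are absent, a decrease in the time column starts
  a new block (both variants occur in the wild).
* gold standard: rows ``regulator<TAB>target<TAB>label`` with label 0 or 1.
* edge ranking: rows ``regulator<TAB>target<TAB>score`` sorted by descending
  score, covering all ordered gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionDataset",
    "GoldStandard",
    "read_timeseries",
    "write_timeseries",
    "read_gold_standard",
    "write_edge_ranking",
    "ranked_edges",
]


@dataclass
class ExpressionDataset:
    """Multi-replicate time-course expression data.

    Attributes
    ----------
    gene_names : list of str
        Ordered gene identifiers, shared by every series.
    series : list of ndarray
        One ``(T_s, G)`` float matrix per replicate time series.
    time_points : list of ndarray
        Per-series time stamps, each of length ``T_s``.
    """

    gene_names: list[str]
    series: list[np.ndarray] = field(default_factory=list)
    time_points: list[np.ndarray] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_series(self) -> int:
        return len(self.series)

    def validate(self) -> "ExpressionDataset":
        if not self.series:
            raise ValueError("dataset has no series")
        g = self.n_genes
        if len(self.time_points) != len(self.series):
            raise ValueError("series and time_points length mismatch")
        for s, (mat, t) in enumerate(zip(self.series, self.time_points)):
            if mat.ndim != 2 or mat.shape[1] != g:
                raise ValueError(f"series {s}: expected {g} gene columns, got shape {mat.shape}")
            if mat.shape[0] < 2:
                raise ValueError(f"series {s}: need at least 2 time points")
            if len(t) != mat.shape[0]:
                raise ValueError(f"series {s}: time stamp count mismatch")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"series {s}: non-finite expression values")
        return self

    def pooled(self) -> np.ndarray:
        """All series concatenated row-wise into one ``(N, G)`` matrix."""
        return np.vstack(self.series)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            gene_names=list(self.gene_names),
            series=[m.copy() for m in self.series],
            time_points=[t.copy() for t in self.time_points],
        )

    def equals(self, other: "ExpressionDataset", rtol: float = 1e-6) -> bool:
        if self.gene_names != other.gene_names or self.n_series != other.n_series:
            return False
        for a, b, ta, tb in zip(self.series, other.series, self.time_points, other.time_points):
            if a.shape != b.shape:
                return False
            if not (np.allclose(a, b, rtol=rtol) and np.allclose(ta, tb, rtol=rtol)):
                return False
        return True


@dataclass
class GoldStandard:
    """True directed edges of a benchmark network.

    ``edges`` holds (regulator_index, target_index) pairs labelled 1;
    every other ordered pair of distinct genes is implicitly a negative.
    """

    n_genes: int
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-pair ({i},{j}) in gold standard")
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes):
                raise ValueError(f"edge ({i},{j}) outside gene range")

    def universe(self) -> list[tuple[int, int]]:
        """All ordered pairs of distinct genes."""
        g = self.n_genes
        return [(i, j) for i in range(g) for j in range(g) if i != j]

    def labels(self, pairs: list[tuple[int, int]] | None = None) -> np.ndarray:
        pairs = self.universe() if pairs is None else pairs
        return np.array([1 if p in self.edges else 0 for p in pairs], dtype=int)


def _parse_block(rows: list[tuple[int, str]], n_cols: int):
    times, values = [], []
    for lineno, line in rows:
        cells = line.rstrip("\n").split("\t")
        if len(cells) != n_cols:
            raise ValueError(
                f"line {lineno}: expected {n_cols} tab-separated fields, got {len(cells)}"
            )
        try:
            nums = [float(c) for c in cells]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric cell ({exc})") from None
        if any(np.isnan(v) for v in nums):
            raise ValueError(f"line {lineno}: missing/NaN value")
        times.append(nums[0])
        values.append(nums[1:])
    return np.asarray(times, dtype=float), np.asarray(values, dtype=float)


def read_timeseries(path, dialect: str = "dream4") -> ExpressionDataset:
    """Read a DREAM4-dialect time-series expression file.

    Replicate boundaries are blank lines; absent those, a decrease in the
    time column starts a new series.
    """
    if dialect != "dream4":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = next((k for k, l in enumerate(lines) if l.strip()), None)
    if header_idx is None:
        raise ValueError("empty file")
    header = lines[header_idx].rstrip("\n").split("\t")
    if not header or header[0].strip().lower() != "time":
        raise ValueError(f"line {header_idx + 1}: first header column must be 'Time'")
    gene_names = [h.strip() for h in header[1:]]
    if not gene_names:
        raise ValueError("no gene columns in header")
    n_cols = len(header)

    blocks: list[list[tuple[int, str]]] = [[]]
    prev_time = None
    for k in range(header_idx + 1, len(lines)):
        line = lines[k]
        if not line.strip():
            if blocks[-1]:
                blocks.append([])
            prev_time = None
            continue
        t = line.split("\t", 1)[0]
        try:
            t_val = float(t)
        except ValueError:
            raise ValueError(f"line {k + 1}: non-numeric time stamp {t!r}") from None
        if prev_time is not None and t_val < prev_time and blocks[-1]:
            blocks.append([])
        prev_time = t_val
        blocks[-1].append((k + 1, line))
    blocks = [b for b in blocks if b]
    if not blocks:
        raise ValueError("file contains a header but no data rows")

    series, time_points = [], []
    for block in blocks:
        t, mat = _parse_block(block, n_cols)
        time_points.append(t)
        series.append(mat)
    return ExpressionDataset(gene_names, series, time_points).validate()


def write_timeseries(dataset: ExpressionDataset, path) -> None:
    """Write a dataset in the DREAM4 time-series dialect (blank-line separated)."""
    dataset.validate()
    with open(path, "w") as fh:
        fh.write("Time\t" + "\t".join(dataset.gene_names) + "\n")
        for s, (mat, t) in enumerate(zip(dataset.series, dataset.time_points)):
            if s:
                fh.write("\n")
            for row_t, row in zip(t, mat):
                cells = [f"{row_t:.10g}"] + [f"{v:.10g}" for v in row]
                fh.write("\t".join(cells) + "\n")


def read_gold_standard(path, gene_names: list[str]) -> GoldStandard:
    """Read a 3-column gold-standard edge list against a known gene order."""
    index = {name: k for k, name in enumerate(gene_names)}
    edges: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields, got {len(cells)}")
            reg, tgt, label = cells[0].strip(), cells[1].strip(), cells[2].strip()
            for name in (reg, tgt):
                if name not in index:
                    raise ValueError(f"line {lineno}: unknown gene {name!r}")
            if reg == tgt:
                raise ValueError(f"line {lineno}: self-loop {reg!r}")
            if label not in {"0", "1"}:
                raise ValueError(f"line {lineno}: label must be 0 or 1, got {label!r}")
            if label == "1":
                edges.add((index[reg], index[tgt]))
    return GoldStandard(n_genes=len(gene_names), edges=edges)


def ranked_edges(scores: np.ndarray, gene_names: list[str]) -> list[tuple[str, str, float]]:
    """All ordered gene pairs sorted by descending score.

    Ties break lexicographically by regulator name, then target name, so the
    output is a deterministic function of the score matrix.
    """
    scores = np.asarray(scores, dtype=float)
    g = len(gene_names)
    if scores.shape != (g, g):
        raise ValueError("score matrix shape does not match gene list")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    rows = [
        (gene_names[i], gene_names[j], float(scores[i, j]))
        for i in range(g)
        for j in range(g)
        if i != j
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows


def write_edge_ranking(scores: np.ndarray, gene_names: list[str], path) -> None:
    """Write the full descending edge ranking as regulator/target/score TSV."""
    with open(path, "w") as fh:
        for reg, tgt, score in ranked_edges(scores, gene_names):
            fh.write(f"{reg}\t{tgt}\t{score:.6e}\n")


def read_edge_ranking(path) -> list[tuple[str, str, float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields")
            rows.append((cells[0], cells[1], float(cells[2])))
    return rows
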