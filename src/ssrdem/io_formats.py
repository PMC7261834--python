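"""Genotype matrices, partitions, and the codominant-marker text formats.

The in-memory model is a dense diploid call array: ``calls[i, l] = (a, b)``
with positive integer allele codes (typically fragment sizes in bp or repeat
numbers) sorted ascending, or ``(-1, -1)`` for a missing call.  Dialect-specific
missing encodings (``0`` / ``000`` in GenePop, ``-9`` in STRUCTURE, empty/``NA``
in CSV) are mapped to the canonical marker at the parsing boundary.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "Partition",
    "GenotypeParseError",
    "GenotypeValidationError",
    "read_genotype_table",
    "write_genotype_table",
]


class GenotypeParseError(ValueError):
    """Malformed input text (bad header, wrong row length, bad token)."""


class GenotypeValidationError(ValueError):
    """Structurally parseable input that violates a matrix invariant."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid codominant genotypes for ``n`` individuals at ``L`` loci.

    Parameters
    ----------
    individuals
        Unique ordered individual identifiers, length ``n``.
    loci
        Unique ordered locus names, length ``L``.
    calls
        ``(n, L, 2)`` integer array.  Non-missing calls hold two positive
        allele codes with ``calls[..., 0] <= calls[..., 1]``; missing calls
        are ``(-1, -1)``.
    """

    individuals: tuple[str, ...]
    loci: tuple[str, ...]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self):
        inds = tuple(str(i) for i in self.individuals)
        loci = tuple(str(l) for l in self.loci)
        calls = np.asarray(self.calls, dtype=np.int64)
        if len(inds) < 1 or len(loci) < 1:
            raise GenotypeValidationError("need at least 1 individual and 1 locus")
        if len(set(inds)) != len(inds):
            dup = next(x for x in inds if inds.count(x) > 1)
            raise GenotypeValidationError(f"duplicate individual identifier: {dup!r}")
        if len(set(loci)) != len(loci):
            dup = next(x for x in loci if loci.count(x) > 1)
            raise GenotypeValidationError(f"duplicate locus name: {dup!r}")
        if calls.shape != (len(inds), len(loci), 2):
            raise GenotypeValidationError(
                f"calls shape {calls.shape} != ({len(inds)}, {len(loci)}, 2)"
            )
        miss = calls[..., 0] == MISSING
        if not np.all(calls[miss] == MISSING):
            raise GenotypeValidationError("half-missing call (one allele coded missing)")
        if np.any(calls[~miss] <= 0):
            raise GenotypeValidationError("allele codes must be positive integers")
        # normalize within-call allele order (unordered pair, smaller first)
        calls = np.sort(calls, axis=2)
        object.__setattr__(self, "individuals", inds)
        object.__setattr__(self, "loci", loci)
        object.__setattr__(self, "calls", calls)
        self.calls.setflags(write=False)

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array, True where the call is missing."""
        return self.calls[..., 0] == MISSING

    def allele_counts(self, locus: int) -> dict[int, int]:
        """Counts of each allele code among non-missing gene copies at a locus."""
        col = self.calls[:, locus, :].ravel()
        col = col[col != MISSING]
        vals, cnt = np.unique(col, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def allele_frequencies(self, locus: int) -> dict[int, float]:
        counts = self.allele_counts(locus)
        tot = sum(counts.values())
        return {a: c / tot for a, c in counts.items()}

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            tuple(self.individuals[i] for i in idx), self.loci, self.calls[idx]
        )

    def subset_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.individuals, tuple(self.loci[i] for i in idx), self.calls[:, idx]
        )

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeMatrix)
            and self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class Partition:
    """Assignment of individuals to non-empty named groups.

    ``labels`` maps individual identifier to group label; ``groups`` fixes the
    group order (first-appearance order by default).
    """

    labels: dict[str, str]
    groups: tuple[str, ...] = ()

    def __post_init__(self):
        labels = {str(k): str(v) for k, v in self.labels.items()}
        groups = tuple(self.groups) or tuple(dict.fromkeys(labels.values()))
        if set(labels.values()) - set(groups):
            missing = sorted(set(labels.values()) - set(groups))
            raise GenotypeValidationError(f"labels use undeclared groups: {missing}")
        empty = [g for g in groups if g not in set(labels.values())]
        if empty:
            raise GenotypeValidationError(f"empty groups: {empty}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "groups", groups)

    def validate_against(self, g: GenotypeMatrix) -> None:
        unknown = set(self.labels) - set(g.individuals)
        if unknown:
            raise GenotypeValidationError(
                f"partition labels individuals absent from the matrix: {sorted(unknown)[:5]}"
            )

    def group_indices(self, g: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Row indices into ``g`` for each group (labeled individuals only)."""
        pos = {ind: i for i, ind in enumerate(g.individuals)}
        out: dict[str, list[int]] = {grp: [] for grp in self.groups}
        for ind, grp in self.labels.items():
            if ind in pos:
                out[grp].append(pos[ind])
        return {grp: np.array(v, dtype=int) for grp, v in out.items() if v}

    def sizes(self) -> dict[str, int]:
        out = {g: 0 for g in self.groups}
        for v in self.labels.values():
            out[v] += 1
        return out


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _as_lines(source) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    return text.replace("\r\n", "\n").replace("\r", "\n").split("\n")


def read_genotype_table(source, dialect: str):
    """Parse a genotype table.

    Parameters
    ----------
    source
        Text stream or string containing the table.
    dialect
        One of ``"csv"``, ``"genepop"``, ``"structure"``.

    Returns
    -------
    (GenotypeMatrix, Partition or None)
        The partition is populated from GenePop ``Pop`` blocks, the STRUCTURE
        second column, or the CSV ``group`` column when present.
    """
    dialect = dialect.lower()
    if dialect == "csv":
        return _read_csv(source)
    if dialect == "genepop":
        return _read_genepop(source)
    if dialect == "structure":
        return _read_structure(source)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_csv(source):
    lines = [ln for ln in _as_lines(source) if ln.strip()]
    if not lines:
        raise GenotypeParseError("empty csv input")
    header = [h.strip() for h in lines[0].split(",")]
    if len(header) < 2 or header[0].lower() != "id":
        raise GenotypeParseError("csv header must start with 'id' (line 1)")
    has_group = len(header) > 1 and header[1].lower() == "group"
    loci = header[2:] if has_group else header[1:]
    if not loci:
        raise GenotypeParseError("csv header declares no loci (line 1)")
    inds, labels, rows = [], {}, []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != len(header):
            raise GenotypeParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        ind = parts[0]
        cells = parts[2:] if has_group else parts[1:]
        if has_group:
            labels[ind] = parts[1]
        row = []
        for li, cell in enumerate(cells):
            if cell in ("", "NA", "na", "0", "0/0", "?"):
                row.append((MISSING, MISSING))
                continue
            try:
                a, b = (int(x) for x in cell.split("/"))
            except Exception:
                raise GenotypeParseError(
                    f"line {lineno}: bad call {cell!r} at locus {loci[li]!r}"
                ) from None
            row.append((a, b))
        inds.append(ind)
        rows.append(row)
    g = GenotypeMatrix(tuple(inds), tuple(loci), np.array(rows, dtype=np.int64))
    part = Partition(labels) if has_group else None
    return g, part


def _split_genepop_alleles(token: str, lineno: int):
    token = token.strip()
    if len(token) in (4, 6) and token.isdigit():
        w = len(token) // 2
        a, b = int(token[:w]), int(token[w:])
    else:
        raise GenotypeParseError(
            f"line {lineno}: genotype token {token!r} is not 4 or 6 digits"
        )
    return (MISSING, MISSING) if a == 0 or b == 0 else (a, b)


def _read_genepop(source):
    lines = _as_lines(source)
    if not lines or not lines[0].strip():
        raise GenotypeParseError("genepop input missing title line")
    # locus names: either one per line, or comma-separated on line 2
    i = 1
    loci: list[str] = []
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenotypeParseError("genepop input declares no loci before first 'Pop'")
    inds, labels, rows = [], {}, []
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        ln = lines[i].strip()
        if ln:
            if pop_idx == 0:
                raise GenotypeParseError(f"line {i + 1}: data before first 'Pop'")
            if "," not in ln:
                raise GenotypeParseError(f"line {i + 1}: missing ',' separator")
            name, rest = ln.split(",", 1)
            tokens = rest.split()
            if len(tokens) != len(loci):
                raise GenotypeParseError(
                    f"line {i + 1}: expected {len(loci)} genotypes, got {len(tokens)}"
                )
            inds.append(name.strip())
            labels[name.strip()] = f"pop{pop_idx}"
            rows.append([_split_genepop_alleles(t, i + 1) for t in tokens])
        i += 1
    if not rows:
        raise GenotypeParseError("genepop input contains no individuals")
    g = GenotypeMatrix(tuple(inds), tuple(loci), np.array(rows, dtype=np.int64))
    return g, Partition(labels)


def _read_structure(source):
    lines = [ln for ln in _as_lines(source) if ln.strip()]
    if len(lines) < 2:
        raise GenotypeParseError("structure input needs a locus header and data rows")
    loci = lines[0].split()
    inds, labels, rows = [], {}, []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != 2 + 2 * len(loci):
            raise GenotypeParseError(
                f"line {lineno}: expected {2 + 2 * len(loci)} fields, got {len(parts)}"
            )
        ind, grp = parts[0], parts[1]
        try:
            vals = [int(x) for x in parts[2:]]
        except ValueError:
            raise GenotypeParseError(f"line {lineno}: non-integer allele code") from None
        row = []
        for li in range(len(loci)):
            a, b = vals[2 * li], vals[2 * li + 1]
            row.append((MISSING, MISSING) if a < 0 or b < 0 or a == 0 or b == 0 else (a, b))
        inds.append(ind)
        labels[ind] = grp
        rows.append(row)
    g = GenotypeMatrix(tuple(inds), tuple(loci), np.array(rows, dtype=np.int64))
    return g, Partition(labels)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_genotype_table(g: GenotypeMatrix, p: Partition | None, dialect: str) -> str:
    """Serialize a matrix (and optional partition) in the named dialect.

    GenePop output requires an explicit partition; pass a one-group partition
    for a single ``Pop`` block.  GenePop allele codes must fit in 3 digits.
    """
    dialect = dialect.lower()
    if p is not None:
        p.validate_against(g)
    if dialect == "csv":
        return _write_csv(g, p)
    if dialect == "genepop":
        return _write_genepop(g, p)
    if dialect == "structure":
        return _write_structure(g, p)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _write_csv(g, p):
    out = io.StringIO()
    has_group = p is not None
    header = ["id"] + (["group"] if has_group else []) + list(g.loci)
    out.write(",".join(header) + "\n")
    for i, ind in enumerate(g.individuals):
        cells = [ind] + ([p.labels.get(ind, "NA")] if has_group else [])
        for l in range(g.n_loci):
            a, b = g.calls[i, l]
            cells.append("" if a == MISSING else f"{a}/{b}")
        out.write(",".join(cells) + "\n")
    return out.getvalue()


def _write_genepop(g, p):
    if p is None:
        raise ValueError(
            "genepop output requires a Partition; pass a one-group partition "
            "explicitly for a single Pop block"
        )
    if int(g.calls.max(initial=0)) > 999:
        raise ValueError("genepop dialect requires allele codes <= 999")
    out = io.StringIO()
    out.write("ssrdem genepop export\n")
    for loc in g.loci:
        out.write(loc + "\n")
    idx = p.group_indices(g)
    for grp in p.groups:
        if grp not in idx:
            continue
        out.write("Pop\n")
        for i in idx[grp]:
            tokens = []
            for l in range(g.n_loci):
                a, b = g.calls[i, l]
                if a == MISSING:
                    tokens.append("000000")
                else:
                    tokens.append(f"{a:03d}{b:03d}")
            out.write(f"{g.individuals[i]} , " + " ".join(tokens) + "\n")
    return out.getvalue()


def _write_structure(g, p):
    out = io.StringIO()
    out.write(" ".join(g.loci) + "\n")
    for i, ind in enumerate(g.individuals):
        grp = p.labels.get(ind, "1") if p is not None else "1"
        vals = []
        for l in range(g.n_loci):
            a, b = g.calls[i, l]
            vals.extend(["-9", "-9"] if a == MISSING else [str(a), str(b)])
        out.write(f"{ind} {grp} " + " ".join(vals) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# result-table helpers
# ---------------------------------------------------------------------------

def frame_to_tsv(df: pd.DataFrame, path=None) -> str:
    """Serialize a result table as TSV (float format stable across runs)."""
    text = df.to_csv(sep="\t", float_format="%.6g")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
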