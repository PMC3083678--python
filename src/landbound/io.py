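"""File formats: Genepop, STRUCTURE, Q-matrices, coordinate tables, rasters,
and the YAML experiment configuration.

Coordinates are serialised 0-based with x = column and y = row; cell centers
sit at integer coordinates.  Genepop is the canonical genotype interchange
(4-digit allele codes); the STRUCTURE two-rows-per-individual format is
provided because spatial clustering programs consume it.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lattice import SampleSet
from .params import SimulationParams

logger = logging.getLogger(__name__)

_MISSING_STRUCTURE = -9


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def write_genepop(sample: SampleSet, path: str | Path,
                  title: str = "landbound export",
                  pop_per_quadrant: bool = True) -> Path:
    """Write a sample as Genepop with 4-digit allele coding.

    Allele IDs are written as ``ID + 1`` (code 0000 means missing in
    Genepop).  When any ID at a locus exceeds 9997 the locus's alleles are
    remapped to ranks and the mapping written to a ``<path>.alleles.csv``
    sidecar.  One POP block per quadrant by default, a single POP otherwise.
    """
    path = Path(path)
    g = sample.genotypes
    n, n_loci, _ = g.shape
    coded = np.empty_like(g)
    mapping_rows = []
    needs_sidecar = False
    for l in range(n_loci):
        alleles = np.unique(g[:, l, :])
        if alleles.max() > 9997:
            needs_sidecar = True
            code_of = {int(a): k + 1 for k, a in enumerate(sorted(alleles))}
            if len(code_of) > 9998:
                raise ValueError(
                    f"locus {l}: {len(code_of)} alleles exceed the 4-digit "
                    "Genepop allele space")
        else:
            code_of = {int(a): int(a) + 1 for a in alleles}
        lut = np.zeros(int(alleles.max()) + 1, dtype=np.int64)
        for a, c in code_of.items():
            lut[a] = c
        coded[:, l, :] = lut[g[:, l, :]]
        mapping_rows.extend((l, a, c) for a, c in sorted(code_of.items()))
    lines = [title]
    lines.extend(f"locus_{l + 1}" for l in range(n_loci))
    order = np.arange(n)
    if pop_per_quadrant:
        order = np.argsort(sample.quadrant, kind="stable")
        pops = sample.quadrant[order]
    else:
        pops = np.zeros(n, dtype=int)
    prev = None
    for idx, pop in zip(order, pops):
        if pop != prev:
            lines.append("POP")
            prev = pop
        geno = " ".join(f"{coded[idx, l, 0]:04d}{coded[idx, l, 1]:04d}"
                        for l in range(n_loci))
        lines.append(f"ind_{idx:04d} , {geno}")
    path.write_text("\n".join(lines) + "\n")
    if needs_sidecar:
        side = path.with_suffix(path.suffix + ".alleles.csv")
        pd.DataFrame(mapping_rows,
                     columns=["locus", "allele_id", "code"]).to_csv(
            side, index=False)
        logger.info("allele IDs above 9997 remapped; mapping in %s", side)
    return path


def read_genepop(path: str | Path) -> tuple[np.ndarray, np.ndarray,
                                            list[str]]:
    """Read a Genepop file; returns (genotypes, pop_labels, locus_names).

    Allele codes are converted back to IDs as ``code - 1``; use the sidecar
    mapping file to recover original IDs when one was written.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("truncated Genepop file")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        locus_names.extend(s.strip() for s in lines[i].split(",")
                           if s.strip())
        i += 1
    genotypes = []
    pops = []
    pop = -1
    for lineno, line in enumerate(lines[i:], start=i + 1):
        s = line.strip()
        if not s:
            continue
        if s.upper() == "POP":
            pop += 1
            continue
        if "," not in s:
            raise ParseError(f"line {lineno}: expected 'name , genotypes'")
        _, geno = s.split(",", 1)
        fields = geno.split()
        if len(fields) != len(locus_names):
            raise ParseError(
                f"line {lineno}: {len(fields)} genotype fields for "
                f"{len(locus_names)} loci")
        row = []
        for f in fields:
            if len(f) not in (4, 6, 8) or not f.isdigit():
                raise ParseError(f"line {lineno}: bad genotype field {f!r}")
            half = len(f) // 2
            row.append((int(f[:half]) - 1, int(f[half:]) - 1))
        genotypes.append(row)
        pops.append(pop)
    return (np.array(genotypes, dtype=np.int64),
            np.array(pops, dtype=np.int64), locus_names)


# ---------------------------------------------------------------------------
# STRUCTURE
# ---------------------------------------------------------------------------

def write_structure(sample: SampleSet, path: str | Path) -> Path:
    """Two-rows-per-individual STRUCTURE format: label, pop (quadrant + 1),
    then one allele code per locus; missing is -9 (unused by the
    simulator)."""
    path = Path(path)
    g = sample.genotypes
    n, n_loci, _ = g.shape
    with open(path, "w") as fh:
        for i in range(n):
            for copy in range(2):
                alleles = " ".join(str(int(g[i, l, copy]) + 1)
                                   for l in range(n_loci))
                fh.write(f"ind_{i:04d} {sample.quadrant[i] + 1} {alleles}\n")
    return path


def read_structure(path: str | Path) -> tuple[np.ndarray, np.ndarray,
                                              list[str]]:
    """Read two-row STRUCTURE data; returns (genotypes, pops, labels)."""
    rows: dict[str, list[tuple[int, list[int]]]] = {}
    labels: list[str] = []
    pops: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        s = line.split()
        if not s:
            continue
        if len(s) < 3:
            raise ParseError(f"line {lineno}: expected label, pop, alleles")
        label = s[0]
        try:
            pop = int(s[1])
            alleles = [int(v) for v in s[2:]]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        if label not in rows:
            rows[label] = []
            labels.append(label)
            pops[label] = pop
        rows[label].append((lineno, alleles))
    n_loci = None
    genotypes = []
    for label in labels:
        entries = rows[label]
        if len(entries) != 2:
            raise ParseError(
                f"individual {label!r} has {len(entries)} rows, expected 2 "
                f"(line {entries[0][0]})")
        a, b = entries[0][1], entries[1][1]
        if n_loci is None:
            n_loci = len(a)
        if len(a) != n_loci or len(b) != n_loci:
            raise ParseError(f"individual {label!r}: inconsistent locus count")
        genotypes.append(np.column_stack([a, b]))
    g = np.array(genotypes, dtype=np.int64) - 1
    g[g == _MISSING_STRUCTURE - 1] = _MISSING_STRUCTURE
    return g, np.array([pops[lb] - 1 for lb in labels]), labels


# ---------------------------------------------------------------------------
# Q-matrices and hard memberships
# ---------------------------------------------------------------------------

def read_qmatrix(path: str | Path):
    """Read a CLUMPP/STRUCTURE-style Q-matrix and harden by argmax.

    Accepts lines of the form ``id [%miss] [(x)] [pop] : q1 q2 ...`` (the
    colon separates metadata from coefficients) or plain whitespace-separated
    ``id q1 q2 ...`` rows.  Rows whose coefficients do not sum to ~1 are
    renormalised with a warning.  Ties in the argmax resolve to the lower
    cluster index.  Returns a :class:`~landbound.evaluation.ClusterResult`.
    """
    from .evaluation import ClusterResult

    coeffs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if ":" in s:
            s = s.split(":", 1)[1]
            fields = s.split()
        else:
            fields = s.split()[1:]  # drop the id column
        try:
            row = [float(v) for v in fields if not v.startswith("(")]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        if not row:
            raise ParseError(f"line {lineno}: no membership coefficients")
        coeffs.append(row)
    if not coeffs:
        raise ParseError("empty Q-matrix file")
    width = len(coeffs[0])
    if any(len(r) != width for r in coeffs):
        raise ParseError("ragged Q-matrix rows")
    q = np.array(coeffs)
    sums = q.sum(axis=1)
    bad = np.abs(sums - 1.0) > 0.02
    if bad.any():
        logger.warning("%d Q-matrix rows do not sum to 1; renormalised",
                       int(bad.sum()))
    q = q / sums[:, None]
    membership = q.argmax(axis=1)
    k = len(np.unique(membership))
    return ClusterResult(k_estimated=k, membership=membership,
                         source=str(path))


def read_hard_assignments(path: str | Path):
    """Read a two-column (id, cluster) CSV of hard memberships."""
    from .evaluation import ClusterResult

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError("expected columns: id, cluster")
    membership = df.iloc[:, 1].to_numpy()
    codes = pd.factorize(membership, sort=True)[0]
    return ClusterResult(k_estimated=len(np.unique(codes)),
                         membership=codes, source=str(path))


# ---------------------------------------------------------------------------
# coordinates and rasters
# ---------------------------------------------------------------------------

def write_coords(sample: SampleSet, path: str | Path) -> Path:
    """Coordinate table: id, x (column), y (row), quadrant; 0-based, cell
    centers at integers."""
    path = Path(path)
    df = pd.DataFrame({
        "id": [f"ind_{i:04d}" for i in range(sample.n_individuals)],
        "x": sample.coords[:, 0],
        "y": sample.coords[:, 1],
        "quadrant": sample.quadrant,
    })
    df.to_csv(path, index=False)
    return path


def read_coords(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ParseError(f"coordinate file lacks columns: {sorted(missing)}")
    return df


def write_raster(array: np.ndarray, path: str | Path) -> Path:
    """Write a gridded surface as a CSV matrix (row 0 = smallest y)."""
    path = Path(path)
    np.savetxt(path, np.asarray(array), delimiter=",", fmt="%.10g")
    return path


def read_raster(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Named parameter combinations plus method settings and a master seed."""

    combos: dict[str, SimulationParams]
    seed: int = 0
    output_dir: str = "landbound_out"
    n_replicates: int | None = None
    methods: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "n_replicates": self.n_replicates,
            "methods": self.methods,
            "combos": {name: asdict(p) for name, p in self.combos.items()},
        }


def write_config(config: ExperimentConfig, path: str | Path) -> Path:
    path = Path(path)
    d = config.to_dict()
    for combo in d["combos"].values():
        combo["export_generations"] = list(combo["export_generations"])
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


def read_config(path: str | Path) -> ExperimentConfig:
    d = yaml.safe_load(Path(path).read_text())
    combos = {}
    for name, fields_ in d.get("combos", {}).items():
        fields_ = dict(fields_)
        if "export_generations" in fields_:
            fields_["export_generations"] = tuple(
                fields_["export_generations"])
        combos[name] = SimulationParams(**fields_)
    return ExperimentConfig(
        combos=combos,
        seed=d.get("seed", 0),
        output_dir=d.get("output_dir", "landbound_out"),
        n_replicates=d.get("n_replicates"),
        methods=d.get("methods", {}),
    )
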