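"""Readers and writers for genotype, phenotype, map and parameter files
and for the three result tables (GREML report, GBLUP table, SNP-effect
table) plus genomic-relationship-matrix files.

All tables are tab-separated text with ``#`` comment lines.  Floating
point values are written with 12 significant digits so a write/read
round trip is the identity at that precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "MarkerMap",
    "RunConfig",
    "ValidationError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "read_marker_map",
    "read_parameter_file",
    "write_greml_report",
    "read_greml_report",
    "write_gblup_table",
    "read_gblup_table",
    "write_snp_effect_table",
    "read_snp_effect_table",
    "write_grm_files",
    "read_grm",
]

#: tokens interpreted as a missing genotype call
MISSING_TOKENS = {"NA", "-9", "5", "NaN", "nan", ""}

#: float formatting used for every numeric table cell
FLOAT_FMT = "{:.12g}"


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


def _fmt(x: float) -> str:
    return FLOAT_FMT.format(float(x))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Allele-dosage codes (count of the A1 allele: 0, 1 or 2) for q
    genotyped individuals at m SNP markers, with a missingness mask."""

    individual_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray        # q x m float array; missing cells hold np.nan
    missing_mask: np.ndarray  # q x m bool

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        q, m = self.codes.shape
        if len(self.individual_ids) != q or len(self.marker_ids) != m:
            raise ValidationError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        if len(set(self.individual_ids)) != q:
            raise ValidationError("duplicate individual id in genotype matrix")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker id in genotype matrix")
        if self.missing_mask.shape != self.codes.shape:
            raise ValidationError("missing_mask shape differs from codes shape")
        observed = self.codes[~self.missing_mask]
        bad = ~np.isin(observed, (0.0, 1.0, 2.0))
        if bad.any():
            rows, cols = np.where(~self.missing_mask)
            k = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"invalid genotype code {observed[bad][0]:g} for individual "
                f"'{self.individual_ids[rows[k]]}' at marker '{self.marker_ids[cols[k]]}'"
            )

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.individual_ids,
            [self.marker_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.marker_ids[i] for i in keep],
            self.codes[:, keep],
            self.missing_mask[:, keep],
        )


@dataclass
class PhenotypeTable:
    """One phenotype record per individual.

    Individuals with an observed trait value form the training set;
    genotyped individuals with a missing trait are the validation set.
    """

    individual_ids: list[str]
    trait: np.ndarray                 # float, np.nan = missing (validation)
    covariates: pd.DataFrame          # untyped until design-matrix construction
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dup = pd.Series(self.individual_ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate phenotype record for individual '{dup}'; "
                "one record per individual is supported"
            )
        if len(self.individual_ids) != len(self.trait):
            raise ValidationError("trait vector length does not match ids")
        if not np.isfinite(self.trait).any():
            raise ValidationError("no training records: every trait value is missing")

    @property
    def training_ids(self) -> list[str]:
        return [i for i, t in zip(self.individual_ids, self.trait) if np.isfinite(t)]

    @property
    def validation_ids(self) -> list[str]:
        return [i for i, t in zip(self.individual_ids, self.trait) if not np.isfinite(t)]


@dataclass
class MarkerMap:
    """Genomic coordinates (chromosome, 1-based bp position) per marker."""

    marker_ids: list[str]
    chromosomes: list[str]
    positions: list[int]

    def __post_init__(self) -> None:
        self._index = {m: k for k, m in enumerate(self.marker_ids)}

    def lookup(self, marker_id: str) -> tuple[str, int]:
        i = self._index.get(marker_id, -1)
        if i < 0:
            return "0", 0
        return self.chromosomes[i], self.positions[i]


@dataclass
class RunConfig:
    """Parsed run parameters (parameter file or API call)."""

    genotype_file: str = ""
    phenotype_file: str = ""
    map_file: str = ""
    trait: str = "trait"
    fixed_effects: list[str] = field(default_factory=list)
    method: str = "auto"              # ce | qm | auto
    grm_definition: int = 1
    em_iterations: int = 2
    max_iterations: int = 200
    tolerance: float = 1e-8
    init_variances: str | tuple[float, float, float] = "auto"
    seed: int = 0
    output_prefix: str = "adgreml"
    emit_snp_effects: bool = True
    threads: int = 1
    genotype_dialect: str = "tsv"

    def __post_init__(self) -> None:
        if self.em_iterations < 2:
            raise ValidationError("em_iterations must be >= 2")
        if not self.tolerance > 0:
            raise ValidationError("tolerance must be positive")
        if self.method not in ("ce", "qm", "auto"):
            raise ValidationError(f"unknown method '{self.method}'")
        if not 1 <= int(self.grm_definition) <= 6:
            raise ValidationError("grm_definition must be an integer in 1..6")


# ---------------------------------------------------------------------------
# genotype file
# ---------------------------------------------------------------------------

_PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(path: str | Path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read an allele-dosage genotype file.

    ``tsv``: header line ``ID<TAB>marker1<TAB>...``, one row per
    individual with codes in {0,1,2} or a missing token (NA, -9, 5).
    ``plink_raw_like``: whitespace-separated with the six PLINK ``.raw``
    leading columns (FID IID PAT MAT SEX PHENOTYPE); the individual id is
    IID and trailing ``_A``-style allele suffixes are stripped from
    marker names.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"genotype file not found: {path}")
    sep = "\t" if dialect == "tsv" else None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"genotype file is empty: {path}")
    header = lines[0].split(sep)
    if dialect == "tsv":
        marker_ids = header[1:]
        first_data_col = 1
        id_col = 0
    elif dialect == "plink_raw_like":
        if len(header) < 7 or [h.upper() for h in header[:2]] != ["FID", "IID"]:
            raise ValidationError(
                f"{path}: plink_raw_like file must start with columns FID IID PAT MAT SEX PHENOTYPE"
            )
        marker_ids = [_strip_allele_suffix(h) for h in header[6:]]
        first_data_col = 6
        id_col = 1
    else:
        raise ValidationError(f"unknown genotype dialect '{dialect}'")

    ids: list[str] = []
    codes = np.zeros((len(lines) - 1, len(marker_ids)))
    mask = np.zeros_like(codes, dtype=bool)
    for r, line in enumerate(lines[1:]):
        tokens = line.split(sep)
        if len(tokens) != first_data_col + len(marker_ids):
            raise ValidationError(
                f"{path}: row {r + 2} has {len(tokens)} fields, expected "
                f"{first_data_col + len(marker_ids)}"
            )
        ids.append(tokens[id_col])
        for c, tok in enumerate(tokens[first_data_col:]):
            if tok in MISSING_TOKENS:
                mask[r, c] = True
                codes[r, c] = np.nan
                continue
            try:
                val = float(tok)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric genotype code '{tok}' for individual "
                    f"'{tokens[id_col]}' at marker '{marker_ids[c]}'"
                ) from None
            if val not in (0.0, 1.0, 2.0):
                raise ValidationError(
                    f"{path}: invalid genotype code '{tok}' for individual "
                    f"'{tokens[id_col]}' at marker '{marker_ids[c]}' (expected 0, 1 or 2)"
                )
            codes[r, c] = val
    return GenotypeMatrix(ids, marker_ids, codes, mask)


def _strip_allele_suffix(name: str) -> str:
    if len(name) > 2 and name[-2] == "_" and name[-1].isalpha():
        return name[:-2]
    return name


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix in the ``tsv`` dialect (missing -> NA)."""
    with open(path, "w") as fh:
        fh.write("ID\t" + "\t".join(G.marker_ids) + "\n")
        for i, ind in enumerate(G.individual_ids):
            row = [
                "NA" if G.missing_mask[i, j] else str(int(G.codes[i, j]))
                for j in range(G.n_markers)
            ]
            fh.write(ind + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# phenotype / map / parameter files
# ---------------------------------------------------------------------------


def read_phenotypes(
    path: str | Path, trait: str, fixed_effects: Sequence[str] = ()
) -> PhenotypeTable:
    """Read a phenotype TSV with an ``ID`` column, the trait column and
    any fixed-effect covariate columns."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    id_col = df.columns[0]
    if trait not in df.columns:
        raise ValidationError(f"{path}: trait column '{trait}' not found")
    for cov in fixed_effects:
        if cov not in df.columns:
            raise ValidationError(f"{path}: fixed-effect column '{cov}' not found")
    trait_vals = pd.to_numeric(df[trait], errors="coerce").to_numpy(dtype=float)
    return PhenotypeTable(
        individual_ids=df[id_col].astype(str).tolist(),
        trait=trait_vals,
        covariates=df[list(fixed_effects)].copy(),
        trait_name=trait,
    )


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a marker map TSV: marker_id, chromosome, position (1-based bp)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"map file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    pos = df.iloc[:, 2].astype(int)
    if (pos <= 0).any():
        raise ValidationError(f"{path}: positions must be positive 1-based integers")
    return MarkerMap(
        marker_ids=df.iloc[:, 0].tolist(),
        chromosomes=df.iloc[:, 1].tolist(),
        positions=pos.tolist(),
    )


_BOOL_KEYS = {"emit_snp_effects"}
_INT_KEYS = {"grm_definition", "em_iterations", "max_iterations", "seed", "threads"}
_FLOAT_KEYS = {"tolerance"}
_LIST_KEYS = {"fixed_effects"}
_KNOWN_KEYS = {
    "genotype_file", "phenotype_file", "map_file", "trait", "fixed_effects",
    "method", "grm_definition", "em_iterations", "max_iterations", "tolerance",
    "init_variances", "seed", "output_prefix", "emit_snp_effects", "threads",
    "genotype_dialect",
}


def read_parameter_file(path: str | Path) -> tuple[RunConfig, list[str]]:
    """Parse a ``key = value`` parameter file.

    Returns the config and a list of warnings (unknown keys are warned
    about, not rejected, for forward compatibility).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"parameter file not found: {path}")
    values: dict[str, object] = {}
    warnings: list[str] = []
    for lineno, raw in enumerate(open(path), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value', got '{raw.strip()}'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in _KNOWN_KEYS:
            warnings.append(f"{path}:{lineno}: unknown parameter '{key}' ignored")
            continue
        if key in _BOOL_KEYS:
            values[key] = val.lower() in ("1", "true", "yes", "on")
        elif key in _INT_KEYS:
            values[key] = int(val)
        elif key in _FLOAT_KEYS:
            values[key] = float(val)
        elif key in _LIST_KEYS:
            values[key] = [v.strip() for v in val.split(",") if v.strip()]
        elif key == "init_variances" and val != "auto":
            parts = [float(v) for v in val.split(",")]
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: init_variances needs 3 comma-separated values or 'auto'"
                )
            values[key] = tuple(parts)
        else:
            values[key] = val
    return RunConfig(**values), warnings


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_greml_report(iteration_records, final, heritabilities, path: str | Path) -> None:
    """Write the GREML iteration trace and the final-estimate block.

    ``iteration_records`` is a sequence of objects with attributes
    ``index, algorithm, theta (sigma2_a, sigma2_d, sigma2_e), logL,
    conv``; ``final`` a VarianceComponents; ``heritabilities`` a
    Heritabilities.
    """
    if not iteration_records:
        raise ValidationError("GREML report requires at least one iteration record")
    buf = io.StringIO()
    buf.write("#adgreml GREML report\n")
    buf.write("iteration\talgorithm\tsigma2_a\tsigma2_d\tsigma2_e\tlogL\tconv\n")
    for rec in iteration_records:
        buf.write(
            f"{rec.index}\t{rec.algorithm}\t{_fmt(rec.theta.sigma2_a)}\t"
            f"{_fmt(rec.theta.sigma2_d)}\t{_fmt(rec.theta.sigma2_e)}\t"
            f"{_fmt(rec.logL)}\t{_fmt(rec.conv)}\n"
        )
    buf.write("#final estimates\n")
    buf.write("parameter\testimate\tse\n")
    se = lambda v: _fmt(v) if v is not None and np.isfinite(v) else "NA"  # noqa: E731
    for name, est, e in [
        ("sigma2_a", final.sigma2_a, final.se_a),
        ("sigma2_d", final.sigma2_d, final.se_d),
        ("sigma2_e", final.sigma2_e, final.se_e),
        ("h2_alpha", heritabilities.h2_alpha, heritabilities.se_h2_alpha),
        ("h2_delta", heritabilities.h2_delta, heritabilities.se_h2_delta),
        ("H2", heritabilities.H2, heritabilities.se_H2),
    ]:
        buf.write(f"{name}\t{_fmt(est)}\t{se(e)}\n")
    Path(path).write_text(buf.getvalue())


def read_greml_report(path: str | Path) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Read back a GREML report: (iteration frame, {parameter: (estimate, se)})."""
    lines = Path(path).read_text().splitlines()
    split = lines.index("#final estimates")
    iters = pd.read_csv(io.StringIO("\n".join(lines[:split])), sep="\t", comment="#")
    finals: dict[str, tuple[float, float]] = {}
    for line in lines[split + 2:]:
        name, est, se = line.split("\t")
        finals[name] = (float(est), float("nan") if se == "NA" else float(se))
    return iters, finals


def write_gblup_table(result, path: str | Path) -> None:
    """Write per-individual GBLUP predictions and reliabilities.

    ``result`` carries ``individual_ids, sets, a_hat, rel_a, d_hat,
    rel_d, g_hat, rel_g``; g_hat must equal a_hat + d_hat row-wise.
    """
    g_check = np.asarray(result.a_hat) + np.asarray(result.d_hat)
    if not np.array_equal(g_check, np.asarray(result.g_hat)):
        raise ValidationError("g_hat must equal a_hat + d_hat exactly")
    with open(path, "w") as fh:
        fh.write("#adgreml GBLUP table\n")
        fh.write("individual_id\tset\ta_hat\trel_a\td_hat\trel_d\tg_hat\trel_g\n")
        for i, ind in enumerate(result.individual_ids):
            fh.write(
                f"{ind}\t{result.sets[i]}\t{_fmt(result.a_hat[i])}\t{_fmt(result.rel_a[i])}\t"
                f"{_fmt(result.d_hat[i])}\t{_fmt(result.rel_d[i])}\t"
                f"{_fmt(result.g_hat[i])}\t{_fmt(result.rel_g[i])}\n"
            )


def read_gblup_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=None, skiprows=2,
                       names=["individual_id", "set", "a_hat", "rel_a", "d_hat",
                              "rel_d", "g_hat", "rel_g"])


def write_snp_effect_table(table, marker_map: MarkerMap | None, path: str | Path) -> None:
    """Write per-SNP effects and heritabilities; markers absent from the
    map get chromosome "0" and position 0."""
    with open(path, "w") as fh:
        fh.write("#adgreml SNP effect table\n")
        fh.write(
            "marker_id\tchromosome\tposition\talpha_hat\tdelta_hat\th2_alpha_i\th2_delta_i\n"
        )
        for i, mid in enumerate(table.marker_ids):
            chrom, pos = marker_map.lookup(mid) if marker_map is not None else ("0", 0)
            fh.write(
                f"{mid}\t{chrom}\t{pos}\t{_fmt(table.alpha_hat[i])}\t"
                f"{_fmt(table.delta_hat[i])}\t{_fmt(table.h2_alpha_i[i])}\t"
                f"{_fmt(table.h2_delta_i[i])}\n"
            )


def read_snp_effect_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=None, skiprows=2,
                       names=["marker_id", "chromosome", "position", "alpha_hat",
                              "delta_hat", "h2_alpha_i", "h2_delta_i"],
                       dtype={"chromosome": str})


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------


def write_grm_files(
    A_g: np.ndarray,
    D_g: np.ndarray,
    individual_ids: Sequence[str],
    definition_id: int,
    prefix: str | Path,
) -> list[Path]:
    """Write A_g and D_g each as a full square TSV and as a long-format
    lower-triangle TSV (id_i, id_j, value for j <= i)."""
    paths = []
    for name, M in (("Ag", A_g), ("Dg", D_g)):
        M = np.asarray(M, dtype=float)
        q = len(individual_ids)
        if M.shape != (q, q):
            raise ValidationError(f"{name} shape {M.shape} does not match {q} individuals")
        if np.abs(M - M.T).max() > 1e-10:
            raise ValidationError(f"{name} is asymmetric beyond 1e-10")
        square = Path(f"{prefix}.{name}.tsv")
        with open(square, "w") as fh:
            fh.write(f"#grm_definition={definition_id}\n")
            fh.write("ID\t" + "\t".join(individual_ids) + "\n")
            for i, ind in enumerate(individual_ids):
                fh.write(ind + "\t" + "\t".join(_fmt(v) for v in M[i]) + "\n")
        long = Path(f"{prefix}.{name}.long.tsv")
        with open(long, "w") as fh:
            fh.write(f"#grm_definition={definition_id}\n")
            fh.write("id_i\tid_j\tvalue\n")
            for i in range(q):
                for j in range(i + 1):
                    fh.write(f"{individual_ids[i]}\t{individual_ids[j]}\t{_fmt(M[i, j])}\n")
        paths += [square, long]
    return paths


def read_grm(path: str | Path) -> tuple[np.ndarray, list[str], int]:
    """Read a square GRM TSV back: (matrix, ids, definition_id)."""
    lines = Path(path).read_text().splitlines()
    definition_id = 0
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#grm_definition="):
            definition_id = int(line.split("=", 1)[1])
        elif not line.startswith("#"):
            body_start = i
            break
    header = lines[body_start].split("\t")
    ids = header[1:]
    rows = [ln.split("\t") for ln in lines[body_start + 1:] if ln]
    M = np.array([[float(v) for v in r[1:]] for r in rows])
    return M, ids, definition_id
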