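"""LC-MS chemomarker analytics: exact-mass auditing and marker ranking.

Two independent jobs live here.  The first is arithmetic: given a molecular
formula, compute the monoisotopic neutral mass and the deprotonated [M-H]-
m/z, and audit an annotation table for internal consistency between its
printed formulas, calculated m/z and ppm mass errors.  The second is
statistical: starting from an exported LC-MS feature table (feature x sample
intensities plus an internal-standard row), normalize to the internal
standard, run a PCA to expose species-separating features, and rank candidate
chemomarkers by one-way ANOVA across species groups.

Mass conventions
----------------
The deprotonated ion m/z is the neutral monoisotopic mass minus the mass of a
neutral hydrogen atom (1.00782503 Da), with no electron-mass correction; this
is the convention the audited annotation tables use.  All rounding is
half-up at the stated number of decimals so printed values are reproducible
bit-for-bit.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from plastomarker.errors import ParseError
from plastomarker.util import round_half_up

#: Monoisotopic atomic masses (Da), pinned for bit-stable output.
MONOISOTOPIC_MASS = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "P": 30.9737615,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a molecular formula like ``C16H18O9`` into element counts.

    Underscores and whitespace (subscript markup artifacts) are ignored.
    Elements are restricted to C, H, N, O, S, P; an omitted count means 1.
    """
    cleaned = text.replace("_", "").replace(" ", "").strip()
    if not cleaned:
        raise ParseError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(cleaned):
        if m.start() != pos:
            raise ParseError(f"unparseable formula {text!r} at {cleaned[pos:]!r}")
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise ParseError(f"unknown element {elem!r} in formula {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = m.end()
        if pos == len(cleaned):
            break
    if pos != len(cleaned):
        raise ParseError(f"unparseable formula {text!r}")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic neutral mass (Da) of a formula, unrounded."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items())


def mz_deprotonated(formula: str | dict[str, int]) -> float:
    """Calculated [M-H]- m/z: neutral mass minus one H atom, half-up at 4 dp."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    if counts.get("H", 0) < 1:
        raise ParseError("formula has no hydrogen: cannot deprotonate")
    return round_half_up(monoisotopic_mass(counts) - MONOISOTOPIC_MASS["H"], 4)


def ppm_error(observed: float, calculated: float) -> float:
    """Mass error 1e6*(obs - calc)/calc in ppm, rounded half-up to 1 dp."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return round_half_up(1e6 * (observed - calculated) / calculated, 1)


@dataclass
class CompoundAnnotation:
    """One annotated LC-MS peak: identity, retention time and mass data."""

    peak_id: str
    name: str
    rt_min: float
    calc_mz: float
    obs_mz: float
    mass_error_ppm: float
    formula: str
    msi_level: int


def audit_annotation_table(rows: list[CompoundAnnotation]) -> pd.DataFrame:
    """Recompute calc m/z and ppm error per row and flag inconsistencies.

    A row is flagged ``inconsistent_mz`` when the printed calculated m/z
    differs from the formula-derived value by more than 0.001 Th — a symptom
    of a typo in either the formula or the m/z column.  Rows whose formula
    cannot be deprotonated (no H) are flagged ``unauditable``.  Nothing is
    corrected; the audit only reports.
    """
    records = []
    for row in rows:
        rec = {
            "peak_id": row.peak_id,
            "name": row.name,
            "formula": row.formula,
            "printed_calc_mz": row.calc_mz,
            "printed_ppm": row.mass_error_ppm,
        }
        try:
            calc = mz_deprotonated(row.formula)
        except ParseError:
            rec.update(recomputed_calc_mz=np.nan, recomputed_ppm=np.nan,
                       flag="unauditable")
        else:
            ppm = ppm_error(row.obs_mz, calc)
            flag = "ok" if abs(calc - row.calc_mz) <= 0.001 else "inconsistent_mz"
            rec.update(recomputed_calc_mz=calc, recomputed_ppm=ppm, flag=flag)
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Feature-table statistics
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Feature x sample LC-MS intensity matrix with sample group metadata.

    ``intensities`` is indexed by feature id with one column per sample;
    ``features`` holds (id, mz, rt); ``sample_meta`` maps each sample column
    to a species group and replicate label; ``is_feature_id`` names the
    internal-standard row used for normalization.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    is_feature_id: str = "IS"
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        if (self.intensities.values < 0).any():
            raise ValueError("intensities must be nonnegative")
        missing = set(self.intensities.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta.loc[self.intensities.columns, "group"]


def normalize_to_is(table: FeatureTable) -> FeatureTable:
    """Divide every sample column by that sample's internal-standard intensity.

    After normalization the IS row is identically 1.0, and any per-sample
    injection/extraction scale factor cancels.
    """
    if table.is_feature_id not in table.intensities.index:
        raise ValueError(f"internal standard {table.is_feature_id!r} not in table")
    is_row = table.intensities.loc[table.is_feature_id]
    bad = is_row[is_row <= 0]
    if len(bad):
        raise ValueError(
            f"internal standard nonpositive in sample(s): {list(bad.index)}")
    norm = table.intensities.divide(is_row, axis=1)
    return FeatureTable(table.features, norm, table.sample_meta,
                        table.is_feature_id, normalized=True)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # features x components
    explained_variance_ratio: np.ndarray


def pca_biplot(table: FeatureTable, n_components: int = 2) -> PCAResult:
    """PCA of log10(x+1)-transformed, mean-centered normalized intensities.

    Zero-variance features are dropped before decomposition.  The sign of
    each component is fixed so that its largest-magnitude loading is
    positive, making scores/loadings reproducible across library versions
    and input orderings.
    """
    from sklearn.decomposition import PCA

    X = np.log10(table.intensities.to_numpy(dtype=float) + 1.0)
    keep = X.var(axis=1) > 0
    X = X[keep]
    feat_ids = table.intensities.index[keep]
    n_samples = X.shape[1]
    if n_samples < n_components:
        raise ValueError("fewer samples than requested components")
    # samples are observations: transpose to samples x features
    Xs = X.T - X.T.mean(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_.T  # features x comps
    for c in range(n_components):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.intensities.columns, columns=cols),
        loadings=pd.DataFrame(loadings, index=feat_ids, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0, 1)
    return q


def anova_markers(table: FeatureTable,
                  candidate_ids: list[str] | None = None,
                  alpha_star: float = 1e-4) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per feature across species groups.

    Returns a DataFrame indexed by feature id with the F statistic, raw p,
    BH q-value, per-group means and a ``significant`` flag at
    ``p < alpha_star`` (the four-star level).  Degenerate features (zero
    variance everywhere with equal group means) and groups with a single
    replicate are skipped with a warning.
    """
    groups = table.groups
    by_group = {g: groups.index[groups == g] for g in groups.unique()}
    if len(by_group) < 2:
        raise ValueError("ANOVA needs at least two groups")
    small = [g for g, cols in by_group.items() if len(cols) < 2]
    if small:
        warnings.warn(f"groups with a single replicate skipped: {small}")
        by_group = {g: c for g, c in by_group.items() if g not in small}
        if len(by_group) < 2:
            raise ValueError("fewer than two groups with >= 2 replicates")

    ids = list(candidate_ids) if candidate_ids is not None else \
        list(table.intensities.index)
    rows, skipped = [], []
    for fid in ids:
        vals = [table.intensities.loc[fid, cols].to_numpy(dtype=float)
                for cols in by_group.values()]
        means = {f"mean_{g}": v.mean() for g, v in zip(by_group, vals)}
        if all(v.std() == 0 for v in vals) and len({v.mean() for v in vals}) == 1:
            skipped.append(fid)
            continue
        f, p = stats.f_oneway(*vals)
        rows.append({"feature": fid, "F": f, "p": p, **means})
    if skipped:
        warnings.warn(f"degenerate features skipped: {skipped[:5]}"
                      + ("..." if len(skipped) > 5 else ""))
    if not rows:
        return pd.DataFrame(columns=["F", "p", "q", "significant"],
                            index=pd.Index([], name="feature"))
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = _bh_qvalues(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha_star
    return out.sort_values("p")


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_feature_table(features_csv, meta_tsv, is_feature_id: str = "IS") -> FeatureTable:
    """Load a feature table CSV (id, mz, rt, then sample columns) + meta TSV."""
    df = pd.read_csv(features_csv)
    df["id"] = df["id"].astype(str)
    feats = df[["id", "mz", "rt"]].copy()
    inten = df.drop(columns=["mz", "rt"]).set_index("id")
    meta = pd.read_csv(meta_tsv, sep="\t").set_index("sample")
    return FeatureTable(feats, inten.astype(float), meta, is_feature_id)


def read_annotation_table(path) -> list[CompoundAnnotation]:
    """Load an annotation CSV with columns peak_id, name, rt_min, calc_mz,
    obs_mz, mass_error_ppm, formula, msi_level."""
    df = pd.read_csv(path)
    return [
        CompoundAnnotation(
            peak_id=str(r.peak_id), name=str(r.name), rt_min=float(r.rt_min),
            calc_mz=float(r.calc_mz), obs_mz=float(r.obs_mz),
            mass_error_ppm=float(r.mass_error_ppm), formula=str(r.formula),
            msi_level=int(r.msi_level),
        )
        for r in df.itertuples(index=False)
    ]
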