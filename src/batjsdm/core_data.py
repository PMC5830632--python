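"""Data model and matrix assembly for the hurdle JSDM pipeline.

The analysis treats one mist-netting session at one site as the sampling
unit.  Raw inputs are four plain-text files:

* ``captures.csv`` — long-format records ``site_id, session_id, period,
  date, species_id, individuals, effort_mnh``;
* ``covariates.csv`` — per site x period habitat class and percentage of
  secondary-forest cover within 500 m;
* ``traits.csv`` — per-species habitat affinity (specialist / generalist);
* ``phylogeny.nwk`` — a newick tree over the modelled species.

This module validates those inputs and assembles the matrices the model
consumes: the binary occurrence matrix ``Y_occ``, the conditional count
matrix ``Y_cond`` (count minus one where present, masked elsewhere), the
session-level design matrix ``X``, the trait design ``T``, the phylogenetic
correlation ``C`` and the session-to-site index.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DataFormatError",
    "DataValidationError",
    "ConsistencyError",
    "CaptureTable",
    "SiteCovariateTable",
    "TraitTable",
    "PhyloCorrelation",
    "ModelData",
    "HABITATS",
    "DESIGN_COLUMNS",
    "load_capture_table",
    "load_covariates",
    "load_traits",
    "phylo_correlation_from_tree",
    "build_design_matrix",
    "build_model_data",
]


class DataFormatError(ValueError):
    """An input file does not match the expected columns/format."""


class DataValidationError(ValueError):
    """An input violates a declared invariant (named row in message)."""


class ConsistencyError(ValueError):
    """Cross-table inconsistency (e.g. species missing from traits/tree)."""


HABITATS = ("continuous", "fragment", "secondary")

#: Fixed column order of the session design matrix (p = 9).  Reference
#: categories are continuous forest and survey period 1.
DESIGN_COLUMNS = (
    "intercept",
    "habitat_fragment",
    "habitat_secondary",
    "period2",
    "sec_cover",
    "log_effort",
    "period2:habitat_fragment",
    "period2:habitat_secondary",
    "period2:sec_cover",
)

_CAPTURE_COLUMNS = ["site_id", "session_id", "period", "date", "species_id",
                    "individuals", "effort_mnh"]


@dataclass
class CaptureTable:
    """Long-format capture records plus the session register.

    ``records`` holds one row per (session, species) with a positive (or,
    exceptionally, zero) number of individuals.  ``sessions`` registers every
    mist-netting session — including sessions that retained no species after
    taxonomic filtering — with its site, survey period and effort in
    mist-net hours (mnh).
    """

    records: pd.DataFrame
    sessions: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.sessions = self.sessions.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        rec, ses = self.records, self.sessions
        for col in ("session_id", "species_id", "individuals"):
            if col not in rec.columns:
                raise DataFormatError(f"records missing column {col!r}")
        for col in ("session_id", "site_id", "period", "effort_mnh"):
            if col not in ses.columns:
                raise DataFormatError(f"sessions missing column {col!r}")
        if ses["session_id"].duplicated().any():
            dup = ses.loc[ses["session_id"].duplicated(), "session_id"].iloc[0]
            raise DataValidationError(f"duplicate session register row: {dup!r}")
        bad = rec.duplicated(subset=["session_id", "species_id"])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValidationError(
                f"(session, species) pair repeated at records row {i}: "
                f"{rec.iloc[i]['session_id']!r}/{rec.iloc[i]['species_id']!r}")
        neg = rec["individuals"] < 0
        if neg.any():
            i = int(np.flatnonzero(neg.to_numpy())[0])
            raise DataValidationError(
                f"negative individuals at records row {i} "
                f"(session {rec.iloc[i]['session_id']!r})")
        bad_eff = ~(ses["effort_mnh"] > 0)
        if bad_eff.any():
            i = int(np.flatnonzero(bad_eff.to_numpy())[0])
            raise DataValidationError(
                f"non-positive effort_mnh for session "
                f"{ses.iloc[i]['session_id']!r}")
        if not (ses["period"].isin([1, 2])).all():
            raise DataValidationError("period must be 1 or 2")
        unknown = ~rec["session_id"].isin(ses["session_id"])
        if unknown.any():
            i = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ConsistencyError(
                f"records row {i} references unregistered session "
                f"{rec.iloc[i]['session_id']!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def species_ids(self) -> list[str]:
        """Sorted (lexicographic) species identifiers present in records."""
        return sorted(self.records["species_id"].unique())

    @property
    def session_ids(self) -> list[str]:
        return sorted(self.sessions["session_id"].unique())

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def total_individuals(self, period: int | None = None) -> int:
        rec = self.records
        if period is not None:
            ses = self.sessions.set_index("session_id")["period"]
            rec = rec[rec["session_id"].map(ses) == period]
        return int(rec["individuals"].sum())

    def count_matrix(self, species_order: list[str] | None = None,
                     session_order: list[str] | None = None) -> np.ndarray:
        """Dense session x species count matrix (rows/cols in given order)."""
        species = list(species_order) if species_order else self.species_ids
        sessions = list(session_order) if session_order else self.session_ids
        smap = {s: i for i, s in enumerate(sessions)}
        pmap = {s: i for i, s in enumerate(species)}
        mat = np.zeros((len(sessions), len(species)), dtype=np.int64)
        for sid, spid, n in self.records[
                ["session_id", "species_id", "individuals"]].itertuples(index=False):
            if sid in smap and spid in pmap:
                mat[smap[sid], pmap[spid]] = int(n)
        return mat

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the long format; all-zero sessions get one placeholder row
        with an empty ``species_id`` and ``individuals`` 0."""
        ses = self.sessions.set_index("session_id")
        rows = []
        with_records = set(self.records["session_id"])
        rec = self.records.merge(
            self.sessions, on="session_id", how="left", suffixes=("", "_s"))
        for r in rec.itertuples(index=False):
            rows.append((r.site_id, r.session_id, r.period,
                         getattr(r, "date", "") or "", r.species_id,
                         int(r.individuals), r.effort_mnh))
        for sid in self.session_ids:
            if sid not in with_records:
                s = ses.loc[sid]
                rows.append((s["site_id"], sid, s["period"],
                             s.get("date", "") or "", "", 0, s["effort_mnh"]))
        out = pd.DataFrame(rows, columns=_CAPTURE_COLUMNS)
        out = out.sort_values(["session_id", "species_id"], kind="stable")
        out.to_csv(path, index=False)


def load_capture_table(path, species_filter: list[str] | None = None) -> CaptureTable:
    """Read ``captures.csv``; optionally restrict to a species subset.

    Sessions whose species are all filtered out are retained as all-zero
    sessions (they still inform the occurrence model).
    """
    try:
        df = pd.read_csv(path, dtype={"site_id": str, "session_id": str,
                                      "species_id": str, "date": str})
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:  # pragma: no cover
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _CAPTURE_COLUMNS if c != "date" and c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s) {missing}")
    if "date" not in df.columns:
        df["date"] = ""
    df["species_id"] = df["species_id"].fillna("")
    if (df["individuals"] < 0).any():
        i = int(df.index[df["individuals"] < 0][0])
        raise DataValidationError(f"{path}: negative individuals at row {i}")
    if (df["effort_mnh"] <= 0).any():
        i = int(df.index[df["effort_mnh"] <= 0][0])
        raise DataValidationError(f"{path}: non-positive effort_mnh at row {i}")

    sessions = (df[["session_id", "site_id", "period", "effort_mnh"]]
                .drop_duplicates(subset="session_id"))
    chk = df.groupby("session_id")[["site_id", "period", "effort_mnh"]].nunique()
    inconsistent = chk[(chk > 1).any(axis=1)]
    if len(inconsistent):
        raise DataValidationError(
            f"{path}: session {inconsistent.index[0]!r} has inconsistent "
            "site/period/effort across rows")

    rec = df[df["species_id"] != ""].copy()
    if species_filter is not None:
        rec = rec[rec["species_id"].isin(set(species_filter))]
    rec = rec[["site_id", "session_id", "period", "date", "species_id",
               "individuals", "effort_mnh"]]
    return CaptureTable(records=rec.reset_index(drop=True), sessions=sessions)


@dataclass
class SiteCovariateTable:
    """Per site x period habitat class and secondary-forest cover (%)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        for col in ("site_id", "period", "habitat", "sec_cover_500m"):
            if col not in t.columns:
                raise DataFormatError(f"covariates missing column {col!r}")
        if t.duplicated(subset=["site_id", "period"]).any():
            raise DataValidationError("duplicate (site_id, period) covariate row")
        if not t["habitat"].isin(HABITATS).all():
            bad = t.loc[~t["habitat"].isin(HABITATS), "habitat"].iloc[0]
            raise DataValidationError(f"unknown habitat class {bad!r}")
        nhab = t.groupby("site_id")["habitat"].nunique()
        if (nhab > 1).any():
            raise DataValidationError(
                f"habitat changes across periods for site {nhab.idxmax()!r}")
        cov = t["sec_cover_500m"]
        if ((cov < 0) | (cov > 100)).any():
            raise DataValidationError("sec_cover_500m outside [0, 100]")
        self.table = t

    def lookup(self, site_id: str, period: int) -> pd.Series:
        t = self.table
        row = t[(t["site_id"] == site_id) & (t["period"] == period)]
        if row.empty:
            raise ConsistencyError(f"no covariates for site {site_id!r}, "
                                   f"period {period}")
        return row.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def load_covariates(path) -> SiteCovariateTable:
    df = pd.read_csv(path, dtype={"site_id": str, "habitat": str})
    return SiteCovariateTable(df)


@dataclass
class TraitTable:
    """Species habitat-affinity labels (the trait matrix T in long form)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        for col in ("species_id", "affinity"):
            if col not in t.columns:
                raise DataFormatError(f"traits missing column {col!r}")
        if t["species_id"].duplicated().any():
            raise DataValidationError("duplicate species in trait table")
        if not t["affinity"].isin(["specialist", "generalist"]).all():
            raise DataValidationError("affinity must be specialist|generalist")
        self.table = t

    def affinity_map(self) -> dict[str, str]:
        return dict(zip(self.table["species_id"], self.table["affinity"]))

    def design(self, species_order: list[str]) -> np.ndarray:
        """S x 2 trait design: intercept and specialist indicator."""
        amap = self.affinity_map()
        missing = [s for s in species_order if s not in amap]
        if missing:
            raise ConsistencyError(f"species missing from traits: {missing[:5]}")
        spec = np.array([amap[s] == "specialist" for s in species_order], float)
        return np.column_stack([np.ones(len(species_order)), spec])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def load_traits(path) -> TraitTable:
    return TraitTable(pd.read_csv(path, dtype=str))


@dataclass
class PhyloCorrelation:
    """Brownian-motion (diffusion) correlation matrix over species.

    ``C[i, k]`` is the root-to-MRCA shared path length of tips *i* and *k*
    divided by the maximum root-to-tip depth, with the diagonal set to 1.
    For an ultrametric tree this is the standard phylogenetic correlation.
    """

    species_order: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        S = len(self.species_order)
        if C.shape != (S, S):
            raise DataValidationError("C shape does not match species_order")
        if not np.allclose(C, C.T, atol=1e-12):
            raise DataValidationError("C is not symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise DataValidationError("C diagonal is not 1")
        if np.linalg.eigvalsh(C).min() <= -1e-10:
            raise DataValidationError("C is not positive definite")
        self.C = C

    def reorder(self, species_order: list[str]) -> "PhyloCorrelation":
        idx = {s: i for i, s in enumerate(self.species_order)}
        missing = [s for s in species_order if s not in idx]
        if missing:
            raise ConsistencyError(f"species missing from phylogeny: {missing[:5]}")
        sel = [idx[s] for s in species_order]
        return PhyloCorrelation(list(species_order),
                                self.C[np.ix_(sel, sel)].copy())


def phylo_correlation_from_tree(newick: str) -> PhyloCorrelation:
    """Correlation matrix under Brownian trait evolution on a newick tree.

    Non-ultrametric trees are accepted; covariances are normalised by the
    maximum root-to-tip depth and the diagonal is then forced to exactly 1.
    """
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        if "duplicate" in str(exc).lower():
            raise DataValidationError(
                "duplicate tip labels in tree") from exc
        raise DataFormatError(f"cannot parse newick tree: {exc}") from exc
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(taxa)) != len(taxa):
        raise DataValidationError("duplicate tip labels in tree")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise DataValidationError("negative branch length in tree")
    depth = {leaf.taxon.label: leaf.root_distance
             for leaf in tree.leaf_node_iter()}
    max_depth = max(depth.values())
    if max_depth <= 0:
        raise DataValidationError("tree has zero total depth")
    order = sorted(taxa)
    S = len(order)
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    C = np.eye(S)
    for i in range(S):
        for k in range(i + 1, S):
            d = pdm.patristic_distance(tax[order[i]], tax[order[k]])
            shared = 0.5 * (depth[order[i]] + depth[order[k]] - d)
            C[i, k] = C[k, i] = shared / max_depth
    return PhyloCorrelation(order, C)


def build_design_matrix(sessions: pd.DataFrame, covars: SiteCovariateTable,
                        *, center_scale: bool = False) -> np.ndarray:
    """Session-level design matrix with the fixed ``DESIGN_COLUMNS`` order.

    Habitat enters as dummies against the continuous-forest reference,
    period as a period-2 dummy, secondary cover as a proportion (value/100),
    effort as its natural log, plus period x habitat and period x cover
    interactions.  ``center_scale`` optionally z-scores the two continuous
    columns (cover proportion and log effort).
    """
    n = len(sessions)
    X = np.zeros((n, len(DESIGN_COLUMNS)))
    for j, row in enumerate(sessions.itertuples(index=False)):
        cv = covars.lookup(row.site_id, int(row.period))
        hab = cv["habitat"]
        cover = float(cv["sec_cover_500m"]) / 100.0
        if not row.effort_mnh > 0:
            raise DataValidationError(
                f"session {row.session_id!r}: effort must be positive "
                "(log transform undefined)")
        p2 = 1.0 if int(row.period) == 2 else 0.0
        frag = 1.0 if hab == "fragment" else 0.0
        sec = 1.0 if hab == "secondary" else 0.0
        X[j] = (1.0, frag, sec, p2, cover, np.log(float(row.effort_mnh)),
                p2 * frag, p2 * sec, p2 * cover)
    if center_scale:
        for col in (4, 5):
            sd = X[:, col].std()
            X[:, col] = (X[:, col] - X[:, col].mean()) / (sd if sd > 0 else 1.0)
    return X


@dataclass
class ModelData:
    """Assembled model matrices, shared by both hurdle submodels.

    ``Y_cond`` holds count − 1 and is meaningful only where ``cond_mask`` is
    True (species present); absent cells are treated as missing data by the
    abundance submodel, never as zeros.
    """

    Y_occ: np.ndarray          # n x S, {0,1}
    Y_cond: np.ndarray         # n x S float, count - 1 where present
    cond_mask: np.ndarray      # n x S bool, True where Y_occ == 1
    X: np.ndarray              # n x p
    T: np.ndarray              # S x q  (intercept, specialist)
    C: PhyloCorrelation        # species-ordered correlation
    site_index: np.ndarray     # n, int site codes
    site_ids: list[str] = field(default_factory=list)
    session_ids: list[str] = field(default_factory=list)
    species_ids: list[str] = field(default_factory=list)
    design_columns: tuple = DESIGN_COLUMNS

    def __post_init__(self) -> None:
        if not np.array_equal(self.cond_mask, self.Y_occ.astype(bool)):
            raise DataValidationError("cond_mask must equal Y_occ == 1")
        if np.any(self.Y_cond[self.cond_mask] < 0):
            raise DataValidationError("conditional counts must be >= 0")
        # X full rank is required (and enforced) at fit time; tiny tables
        # with fewer sessions than design columns are legal containers.

    @property
    def n_sessions(self) -> int:
        return self.Y_occ.shape[0]

    @property
    def n_species(self) -> int:
        return self.Y_occ.shape[1]

    @property
    def n_sites(self) -> int:
        return len(np.unique(self.site_index))


def build_model_data(captures: CaptureTable, covars: SiteCovariateTable,
                     traits: TraitTable, phylo: PhyloCorrelation,
                     *, center_scale: bool = False) -> ModelData:
    """Assemble Y/X/T/C and the site index from validated inputs.

    The hurdle split: ``Y_occ = 1`` iff the count is positive; where present,
    ``Y_cond`` is the count minus one (so its support starts at zero, matching
    the overdispersed-Poisson submodel); absent cells are masked.
    """
    species = captures.species_ids
    sessions = captures.sessions.sort_values("session_id").reset_index(drop=True)
    counts = captures.count_matrix(species_order=species,
                                   session_order=list(sessions["session_id"]))
    Y_occ = (counts > 0).astype(np.int8)
    mask = counts > 0
    Y_cond = np.where(mask, counts - 1, np.nan).astype(float)
    X = build_design_matrix(sessions, covars, center_scale=center_scale)
    T = traits.design(species)
    C = phylo.reorder(species)
    site_ids = sorted(sessions["site_id"].unique())
    smap = {s: i for i, s in enumerate(site_ids)}
    site_index = sessions["site_id"].map(smap).to_numpy(dtype=int)
    return ModelData(Y_occ=Y_occ, Y_cond=Y_cond, cond_mask=mask, X=X, T=T,
                     C=C, site_index=site_index, site_ids=site_ids,
                     session_ids=list(sessions["session_id"]),
                     species_ids=species)
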