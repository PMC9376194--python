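"""Cohort data model and on-disk formats.

A cohort is an ordered collection of subjects, each carrying a regional
time-series matrix (regions x timepoints, BOLD-like units), a binary class
label, an acquisition-site name, and optional symptom-domain scores and
head-motion summaries. All on-disk artifacts are plain TSV: a manifest with
a header row, and one headerless numeric matrix file per subject (regions
as rows, timepoints as columns).

The number of regions must agree across a cohort; the number of timepoints
may differ between subjects and sites, as is typical for multi-site fMRI.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_TIMEPOINTS = 8

#: Manifest columns, in file order. Score and motion columns are optional;
#: empty cells mean "missing".
MANIFEST_REQUIRED = ("subject_id", "timeseries_path", "class_label", "site")
SCORE_PREFIX = "score_"


class CohortValidationError(ValueError):
    """A cohort or manifest violates a structural invariant."""


@dataclass
class SubjectRecord:
    """One subject: a regions x timepoints matrix plus metadata.

    Parameters
    ----------
    subject_id : str
        Unique identifier within the cohort.
    timeseries : ndarray, shape (n_regions, n_timepoints)
        Regional time series; any real-valued BOLD-like units.
    class_label : int
        Binary group membership, 0 or 1.
    site : str
        Acquisition-site name.
    symptom_scores : dict
        Symptom-domain name -> score; missing domains are absent keys.
    mean_fd : float or None
        Mean framewise displacement (mm), if available.
    """

    subject_id: str
    timeseries: np.ndarray
    class_label: int
    site: str
    symptom_scores: dict[str, float] = field(default_factory=dict)
    mean_fd: float | None = None

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        if self.timeseries.ndim != 2:
            raise CohortValidationError(
                f"subject {self.subject_id}: timeseries must be 2-D "
                f"(regions x timepoints), got shape {self.timeseries.shape}"
            )
        if self.timeseries.shape[1] < MIN_TIMEPOINTS:
            raise CohortValidationError(
                f"subject {self.subject_id}: needs >= {MIN_TIMEPOINTS} "
                f"timepoints, got {self.timeseries.shape[1]}"
            )
        if int(self.class_label) not in (0, 1):
            raise CohortValidationError(
                f"subject {self.subject_id}: class_label must be 0 or 1"
            )
        self.class_label = int(self.class_label)

    @property
    def n_regions(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.timeseries.shape[1]


@dataclass
class Cohort:
    """Ordered collection of subjects with shared region definitions."""

    subjects: list[SubjectRecord]
    region_names: list[str]
    site_vocabulary: list[str]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise CohortValidationError("cohort must contain >= 1 subject")
        nc = self.subjects[0].n_regions
        bad = [s.subject_id for s in self.subjects if s.n_regions != nc]
        if bad:
            raise CohortValidationError(
                f"inconsistent region count: expected {nc} regions, "
                f"offending subjects: {', '.join(bad)}"
            )
        if len(self.region_names) != nc:
            raise CohortValidationError(
                f"region_names has {len(self.region_names)} entries, "
                f"cohort has {nc} regions"
            )
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dupes}")
        missing = {s.site for s in self.subjects} - set(self.site_vocabulary)
        if missing:
            raise CohortValidationError(
                f"sites not covered by site_vocabulary: {sorted(missing)}"
            )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_regions(self) -> int:
        return self.subjects[0].n_regions

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.class_label for s in self.subjects], dtype=int)

    @property
    def sites(self) -> list[str]:
        return [s.site for s in self.subjects]

    @property
    def min_timepoints(self) -> int:
        return min(s.n_timepoints for s in self.subjects)

    def subset(self, indices) -> "Cohort":
        """New cohort with the selected subjects, preserving metadata."""
        subs = [self.subjects[i] for i in indices]
        return Cohort(subs, list(self.region_names), list(self.site_vocabulary))

    @property
    def domains(self) -> list[str]:
        """Symptom-domain names present on any subject, sorted."""
        names: set[str] = set()
        for s in self.subjects:
            names.update(s.symptom_scores)
        return sorted(names)


@dataclass
class SiteEncoding:
    """One-hot site rows for an ordered vocabulary.

    Rows for in-vocabulary sites contain exactly one 1; rows for sites
    absent from the vocabulary are all-zero. The all-zero convention lets a
    model trained on one site set score subjects from entirely new sites
    without retraining: the site term simply contributes nothing.
    """

    vocabulary: list[str]
    matrix: np.ndarray  # (n_subjects, len(vocabulary))


def encode_sites(cohort: Cohort, vocabulary: list[str] | None = None) -> SiteEncoding:
    """One-hot encode each subject's acquisition site.

    Unseen sites (not in ``vocabulary``) map to an all-zero row.
    """
    if vocabulary is None:
        vocabulary = list(cohort.site_vocabulary)
    if not vocabulary:
        raise CohortValidationError("site vocabulary must be non-empty")
    if len(set(vocabulary)) != len(vocabulary):
        raise CohortValidationError("site vocabulary contains duplicates")
    index = {name: j for j, name in enumerate(vocabulary)}
    mat = np.zeros((len(cohort), len(vocabulary)))
    for i, s in enumerate(cohort):
        j = index.get(s.site)
        if j is not None:
            mat[i, j] = 1.0
    return SiteEncoding(list(vocabulary), mat)


def encode_site_name(site: str, vocabulary: list[str]) -> np.ndarray:
    """One-hot row for a single site name (all-zero if unseen)."""
    row = np.zeros(len(vocabulary))
    if site in vocabulary:
        row[vocabulary.index(site)] = 1.0
    return row


def zscore_normalize(cohort: Cohort) -> Cohort:
    """Standardize every region's time series, per subject, to mean 0 / sd 1.

    Constant rows map to all-zeros rather than NaN so that downstream
    convolutions never see non-finite values. Uses the population standard
    deviation (ddof=0), which makes the transform idempotent.
    """
    out = []
    for s in cohort:
        ts = s.timeseries
        if not np.all(np.isfinite(ts)):
            raise CohortValidationError(
                f"subject {s.subject_id}: non-finite values in time series"
            )
        mu = ts.mean(axis=1, keepdims=True)
        sd = ts.std(axis=1, keepdims=True)
        z = np.where(sd > 0, (ts - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out.append(dataclasses.replace(s, timeseries=z))
    return Cohort(out, list(cohort.region_names), list(cohort.site_vocabulary))


# ---------------------------------------------------------------------------
# Disk I/O


def save_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> str:
    """Write a cohort as manifest.tsv + one TSV matrix per subject.

    Values are written at full double precision (%.17g) so a save/load
    round trip is bit-exact. Returns the manifest path.
    """
    out_dir = os.fspath(out_dir)
    ts_dir = os.path.join(out_dir, "timeseries")
    os.makedirs(ts_dir, exist_ok=True)
    domains = cohort.domains
    rows = []
    for s in cohort:
        rel = os.path.join("timeseries", f"{s.subject_id}.tsv")
        np.savetxt(os.path.join(out_dir, rel), s.timeseries,
                   delimiter="\t", fmt="%.17g")
        row = {
            "subject_id": s.subject_id,
            "timeseries_path": rel,
            "class_label": s.class_label,
            "site": s.site,
        }
        for d in domains:
            v = s.symptom_scores.get(d)
            row[SCORE_PREFIX + d] = "" if v is None else repr(float(v))
        row["mean_fd"] = "" if s.mean_fd is None else repr(float(s.mean_fd))
        rows.append(row)
    manifest = os.path.join(out_dir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    with open(os.path.join(out_dir, "region_names.txt"), "w") as fh:
        fh.write("\n".join(cohort.region_names) + "\n")
    return manifest


def _load_matrix(path: str, subject_id: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"time-series file for subject {subject_id} not found: {path}"
        )
    try:
        return np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise CohortValidationError(
            f"non-numeric cell in {path} (subject {subject_id}): {exc}"
        ) from exc


def load_cohort(manifest_path: str | os.PathLike) -> Cohort:
    """Load a cohort from a manifest TSV.

    The manifest needs columns subject_id, timeseries_path, class_label and
    site; any ``score_<domain>`` columns become symptom scores and a
    ``mean_fd`` column becomes the motion summary (empty cells = missing).
    Time-series paths are resolved relative to the manifest's directory.
    """
    manifest_path = os.fspath(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    df = pd.read_csv(manifest_path, sep="\t",
                     dtype={"subject_id": str, "site": str},
                     float_precision="round_trip")
    missing_cols = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"manifest missing columns: {missing_cols}")
    score_cols = [c for c in df.columns if c.startswith(SCORE_PREFIX)]
    subjects = []
    for _, row in df.iterrows():
        ts = _load_matrix(os.path.join(base, str(row["timeseries_path"])),
                          str(row["subject_id"]))
        scores = {}
        for c in score_cols:
            v = row[c]
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                scores[c[len(SCORE_PREFIX):]] = float(v)
        fd = row.get("mean_fd")
        fd = None if fd is None or (isinstance(fd, float) and math.isnan(fd)) else float(fd)
        subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]), timeseries=ts,
            class_label=int(row["class_label"]), site=str(row["site"]),
            symptom_scores=scores, mean_fd=fd))
    names_file = os.path.join(base, "region_names.txt")
    if os.path.exists(names_file):
        with open(names_file) as fh:
            region_names = [ln.strip() for ln in fh if ln.strip()]
    else:
        region_names = [f"region{r:03d}" for r in range(subjects[0].n_regions)]
    vocab = list(dict.fromkeys(s.site for s in subjects))
    return Cohort(subjects, region_names, vocab)
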