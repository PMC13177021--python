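"""QTAIM bond-critical-point tables: derived energy densities,
interaction classification and cross-condition comparison.

A bond critical point (BCP) is a saddle point of the electron density
between two nuclei.  Its local properties — electron density ρ, Laplacian
∇²ρ, Lagrangian kinetic energy density G ≥ 0, Hamiltonian kinetic energy
density K and potential energy density V = −G − K — characterize the
interaction.  The total energy density is H = G + V (= −K); ∇²ρ marks
density concentration (negative) or depletion (positive).

Interactions are classified in the Kumar scheme: closed-shell, noncovalent
contacts have ∇²ρ > 0 and H > 0; partially covalent hydrogen bonds have
∇²ρ > 0 but H < 0; covalent (shared-shell) interactions have ∇²ρ < 0 and
H < 0.  Degenerate zero values are resolved through the −G/V ratio
(> 1 noncovalent, (0.5, 1] partially covalent, ≤ 0.5 covalent).

All quantities are consumed in atomic units; no conversion is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NONCOVALENT = "noncovalent"
PARTIALLY_COVALENT = "partially_covalent"
COVALENT = "covalent"
INCONSISTENT = "inconsistent"

LABELS = (NONCOVALENT, PARTIALLY_COVALENT, COVALENT)

#: Tolerance of the V = −G − K consistency check, a.u.
CONSISTENCY_TOL = 1e-8


@dataclass(frozen=True)
class ClassificationThresholds:
    """Tunable cutoffs of the BCP classifier.

    ``zero_tol`` decides when ∇²ρ or H count as zero; the ratio cutoffs
    partition −G/V into the three classes in the degenerate branch.
    """

    zero_tol: float = 0.0
    ratio_noncovalent: float = 1.0
    ratio_covalent: float = 0.5


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass
class BCPRecord:
    """One bond critical point with its derived quantities and class label."""

    rho: float
    laplacian: float
    G: float
    K: float
    V: float
    H: float
    ratio: float
    label: str | None = None


def potential_energy_density(G: float, K: float) -> float:
    """V = −G − K, the local potential energy density at the BCP (a.u.)."""
    return -G - K


def make_record(rho: float, laplacian: float, G: float,
                K: float | None = None, V: float | None = None,
                thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
                ) -> BCPRecord:
    """Assemble a consistent :class:`BCPRecord` from a property row.

    Exactly one of K, V may be omitted; it is derived from V = −G − K.
    When all three are supplied they must satisfy the identity within
    ``CONSISTENCY_TOL``.

    Raises
    ------
    ValueError
        On G < 0, a missing pair, or an inconsistent (G, K, V) triple.
    """
    if G < 0:
        raise ValueError(f"G must be non-negative, got {G}")
    if K is None and V is None:
        raise ValueError("need at least one of K, V")
    if K is None:
        K = -G - V  # type: ignore[operator]
    elif V is None:
        V = potential_energy_density(G, K)
    elif abs(V + G + K) > CONSISTENCY_TOL:
        raise ValueError(
            f"inconsistent triple: V + G + K = {V + G + K:.3e} (tol "
            f"{CONSISTENCY_TOL:g})")
    H = G + V
    ratio = -G / V if V != 0 else (np.inf if G > 0 else np.nan)
    rec = BCPRecord(rho=rho, laplacian=laplacian, G=G, K=float(K),
                    V=float(V), H=float(H), ratio=float(ratio))
    rec.label = classify_bcp(rec, thresholds)
    return rec


def classify_bcp(record: BCPRecord,
                 thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
                 ) -> str:
    """Class label of a BCP from the signs of ∇²ρ and H.

    ∇²ρ > 0, H > 0 → noncovalent; ∇²ρ > 0, H < 0 → partially covalent;
    ∇²ρ < 0, H < 0 → covalent.  When either quantity sits at zero (within
    ``zero_tol``) the −G/V ratio decides.  The physically inconsistent
    combination ∇²ρ < 0 with H > 0 is flagged as ``"inconsistent"``
    (returned, not raised).
    """
    zt = thresholds.zero_tol
    lap, H = record.laplacian, record.H
    if abs(lap) <= zt or abs(H) <= zt:
        r = record.ratio
        if r > thresholds.ratio_noncovalent:
            return NONCOVALENT
        if r > thresholds.ratio_covalent:
            return PARTIALLY_COVALENT
        return COVALENT
    if lap > 0:
        return NONCOVALENT if H > 0 else PARTIALLY_COVALENT
    return COVALENT if H < 0 else INCONSISTENT


_COLUMN_ALIASES = {
    "rho": "rho", "density": "rho", "rho(r)": "rho",
    "laplacian": "laplacian", "del2rho": "laplacian", "lap": "laplacian",
    "laplacian_rho": "laplacian", "nabla2rho": "laplacian",
    "g": "G", "g(r)": "G", "k": "K", "k(r)": "K", "v": "V", "v(r)": "V",
    "label": "label", "group": "group",
}


def read_bcp_table(path_or_buffer, sep: str | None = None,
                   thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
                   ) -> list[BCPRecord]:
    """Parse a delimited BCP property table into classified records.

    The header must name (case-insensitively) at least rho, laplacian, G
    and one of K, V; a missing member of the (K, V) pair is derived from
    V = −G − K.  The delimiter is sniffed when not given.

    Raises
    ------
    ValueError
        On missing required columns, negative G, or an inconsistent
        (G, K, V) triple.
    """
    df = pd.read_csv(path_or_buffer, sep=sep, engine="python")
    cols = {}
    for c in df.columns:
        key = _COLUMN_ALIASES.get(str(c).strip().lower())
        if key:
            cols[key] = c
    missing = {"rho", "laplacian", "G"} - set(cols)
    if missing or not ({"K", "V"} & set(cols)):
        raise ValueError(
            f"table must provide rho, laplacian, G and one of K, V; "
            f"missing {sorted(missing) or ['K or V']}")
    records = []
    for _, row in df.iterrows():
        records.append(make_record(
            rho=float(row[cols["rho"]]),
            laplacian=float(row[cols["laplacian"]]),
            G=float(row[cols["G"]]),
            K=float(row[cols["K"]]) if "K" in cols else None,
            V=float(row[cols["V"]]) if "V" in cols else None,
            thresholds=thresholds))
    return records


def write_bcp_table(records: list[BCPRecord], path, sep: str = ",") -> None:
    """Write records as a delimited table re-readable by read_bcp_table."""
    df = pd.DataFrame({
        "rho": [r.rho for r in records],
        "laplacian": [r.laplacian for r in records],
        "G": [r.G for r in records],
        "K": [r.K for r in records],
        "V": [r.V for r in records],
        "label": [r.label for r in records],
    })
    df.to_csv(path, sep=sep, index=False)


def summarize_classes(records: list[BCPRecord],
                      groups: list | None = None) -> pd.DataFrame:
    """Percentage of each interaction class, overall or per group.

    Returns a DataFrame indexed by group with one column per class label,
    rows summing to 100.

    Raises
    ------
    ValueError
        On an empty record list or a group list of mismatched length.
    """
    if not records:
        raise ValueError("no records to summarize")
    if groups is None:
        groups = ["all"] * len(records)
    if len(groups) != len(records):
        raise ValueError("groups must match records in length")
    df = pd.DataFrame({"label": [r.label for r in records], "group": groups})
    out = {}
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        out[g] = {lab: 100.0 * (sub["label"] == lab).sum() / n
                  for lab in LABELS}
        extra = set(sub["label"]) - set(LABELS)
        for lab in sorted(extra):
            out[g][lab] = 100.0 * (sub["label"] == lab).sum() / n
    return pd.DataFrame(out).T.fillna(0.0)


@dataclass
class GroupComparison:
    """Omnibus test outcome for one property across conditions."""

    p_value: float
    statistic: float
    test: str


def compare_groups(groups: list, test: str = "kruskal") -> GroupComparison:
    """Omnibus p-value of a property across >= 2 condition groups.

    Kruskal–Wallis by default (rank-based, robust to non-normality);
    one-way ANOVA with ``test="anova"``.  If every observation in every
    group is identical the test statistic is undefined and p = 1 is
    returned with a warning.

    Raises
    ------
    ValueError
        On fewer than 2 groups or groups with fewer than 2 observations.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; p set to 1")
        return GroupComparison(p_value=1.0, statistic=0.0, test=test)
    if test == "kruskal":
        stat, p = stats.kruskal(*arrays)
    elif test == "anova":
        stat, p = stats.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(p_value=float(p), statistic=float(stat), test=test)
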