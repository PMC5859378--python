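"""SNP-based parentage assignment for a partial factorial cross.

Every candidate sire x dam pair is scored against each offspring by the
trio-incompatibility rate: the fraction of loci (all three genotypes
non-missing) at which the offspring dosage cannot arise from any
combination of parental gametes.  An offspring is uniquely assigned when
the best pair's rate is below the genotyping-error tolerance and beats the
runner-up by a margin.

The incompatible trio configurations, derived by enumerating parental
gametes (dosage 0 -> gamete {0}, 1 -> {0,1}, 2 -> {1}), decompose into
(a) an opposing homozygote between the offspring and either single parent,
or (b) both parents homozygous for the same allele with a heterozygous
offspring.  That decomposition lets the all-pairs score be computed with a
handful of one-hot matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree

#: trio dosage triples (sire, dam, offspring) impossible under Mendelian
#: inheritance, from exhaustive gamete enumeration.
INCOMPATIBLE_TRIOS = frozenset({
    (0, 0, 1), (0, 0, 2),
    (2, 2, 0), (2, 2, 1),
    (0, 2, 0), (0, 2, 2), (2, 0, 0), (2, 0, 2),
    (0, 1, 2), (1, 0, 2), (1, 2, 0), (2, 1, 0),
})


def trio_mismatch_rate(offspring: np.ndarray, sire: np.ndarray, dam: np.ndarray
                       ) -> tuple[float, int, int]:
    """Mismatch rate of a single trio over the shared locus index.

    Returns (rate, n_mismatch, n_compared); rate is NaN when no locus has
    all three genotypes present.
    """
    o = np.asarray(offspring)
    s = np.asarray(sire)
    d = np.asarray(dam)
    ok = (o != MISSING) & (s != MISSING) & (d != MISSING)
    n_comp = int(ok.sum())
    if n_comp == 0:
        return float("nan"), 0, 0
    opp_s = np.abs(o - s) == 2
    opp_d = np.abs(o - d) == 2
    hh = (s == d) & ((s == 0) | (s == 2)) & (o == 1)
    mism = int((ok & (opp_s | opp_d | hh)).sum())
    return mism / n_comp, mism, n_comp


def _onehot(d: np.ndarray, value: int) -> np.ndarray:
    return (d == value).astype(np.float32)


def _pair_mismatch_counts(off: np.ndarray, sires: np.ndarray, dams: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch and comparable-locus counts for every offspring x (sire, dam).

    Inputs are raw dosage arrays; returns two ``(n_off, n_sires * n_dams)``
    arrays, pair index ``s * n_dams + d``.  Exact integer counts computed in
    float32 BLAS (values stay far below float32's exact-integer range).
    """
    ns, nd = sires.shape[0], dams.shape[0]
    o0, o1, o2 = _onehot(off, 0), _onehot(off, 1), _onehot(off, 2)
    ons = (off != MISSING).astype(np.float32)
    s0, s2 = _onehot(sires, 0), _onehot(sires, 2)
    d0, d2 = _onehot(dams, 0), _onehot(dams, 2)
    sns = (sires != MISSING).astype(np.float32)
    dns = (dams != MISSING).astype(np.float32)

    # single-parent opposing homozygotes, restricted to loci where the other
    # parent is also genotyped (trio-complete loci only)
    m = off.shape[1]
    sd_nn = (sns[:, None, :] * dns[None, :, :]).reshape(ns * nd, m)
    sd_00 = (s0[:, None, :] * d0[None, :, :]).reshape(ns * nd, m)
    sd_22 = (s2[:, None, :] * d2[None, :, :]).reshape(ns * nd, m)
    sd_s2 = (s2[:, None, :] * dns[None, :, :]).reshape(ns * nd, m)
    sd_s0 = (s0[:, None, :] * dns[None, :, :]).reshape(ns * nd, m)
    sd_d2 = (sns[:, None, :] * d2[None, :, :]).reshape(ns * nd, m)
    sd_d0 = (sns[:, None, :] * d0[None, :, :]).reshape(ns * nd, m)

    # opposing homozygotes with sire or dam (union = sum - both), plus the
    # both-parents-homozygous / heterozygous-offspring case
    mm = (
        o0 @ (sd_s2 + sd_d2 - sd_22).T  # sd_22 counted twice in the union
        + o2 @ (sd_s0 + sd_d0 - sd_00).T
        + o1 @ (sd_00 + sd_22).T
    )
    comp = ons @ sd_nn.T
    return np.rint(mm).astype(np.int64), np.rint(comp).astype(np.int64)


@dataclass
class AssignmentResult:
    """Per-offspring best parental pair and the derived pedigree."""

    table: pd.DataFrame  # offspring_id, sire_id, dam_id, mismatch_rate, runner_up_rate, n_compared, status

    @property
    def n_assigned(self) -> int:
        return int((self.table["status"] == "assigned").sum())

    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "assigned"]

    def to_pedigree(self, parent_blocks: dict | None = None) -> Pedigree:
        """Pedigree of assigned offspring plus their parents as founders."""
        a = self.assigned()
        parents = pd.unique(pd.concat([a["sire_id"], a["dam_id"]]))
        rows = [(p, UNKNOWN, UNKNOWN, (parent_blocks or {}).get(p, 0)) for p in parents]
        rows += [
            (r.offspring_id, r.sire_id, r.dam_id,
             (parent_blocks or {}).get(r.sire_id, 0))
            for r in a.itertuples()
        ]
        return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "block"]))

    def family_summary(self) -> dict:
        a = self.assigned()
        fam = a.groupby(["sire_id", "dam_id"]).size()
        return {
            "n_assigned": self.n_assigned,
            "n_families": int(len(fam)),
            "family_size_min": int(fam.min()) if len(fam) else 0,
            "family_size_max": int(fam.max()) if len(fam) else 0,
            "family_size_mean": float(fam.mean()) if len(fam) else 0.0,
            "sire_contributions": a.groupby("sire_id").size().to_dict(),
            "dam_contributions": a.groupby("dam_id").size().to_dict(),
        }


def assign_parents(offspring: GenotypeMatrix, candidate_sires: GenotypeMatrix,
                   candidate_dams: GenotypeMatrix, tolerance: float = 0.04,
                   margin: float = 0.01) -> AssignmentResult:
    """Assign each offspring to its minimal-mismatch sire-dam pair.

    A pair is accepted iff its mismatch rate is <= ``tolerance`` and the
    runner-up pair's rate exceeds it by at least ``margin`` (uniqueness);
    otherwise the offspring is ``ambiguous`` (tolerable best but no margin)
    or ``unassigned``.  Ties are never broken by candidate order.
    """
    if not 0 <= tolerance <= 1:
        raise ValueError("tolerance must be in [0, 1]")
    if candidate_sires.n_samples == 0 or candidate_dams.n_samples == 0:
        raise ValueError("empty candidate parent set")
    mm, comp = _pair_mismatch_counts(
        offspring.dosages, candidate_sires.dosages, candidate_dams.dosages
    )
    nd = candidate_dams.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(comp > 0, mm / np.maximum(comp, 1), np.nan)

    rows = []
    for i, oid in enumerate(offspring.samples):
        r = rates[i]
        if np.all(np.isnan(r)):
            rows.append((oid, None, None, np.nan, np.nan, 0, "unassigned"))
            continue
        best = int(np.nanargmin(r))
        best_rate = float(r[best])
        others = np.delete(r, best)
        runner = float(np.nanmin(others)) if others.size and not np.all(np.isnan(others)) else np.nan
        sire_id = candidate_sires.samples[best // nd]
        dam_id = candidate_dams.samples[best % nd]
        if best_rate <= tolerance:
            unique = np.isnan(runner) or (runner - best_rate) >= margin
            status = "assigned" if unique else "ambiguous"
        else:
            status = "unassigned"
        if status != "assigned":
            sire_id = dam_id = None
        rows.append((oid, sire_id, dam_id, best_rate, runner, int(comp[i, best]), status))

    table = pd.DataFrame(
        rows,
        columns=["offspring_id", "sire_id", "dam_id", "mismatch_rate",
                 "runner_up_rate", "n_compared", "status"],
    )
    return AssignmentResult(table)


def validate_pedigree(pedigree: Pedigree, g: GenotypeMatrix, threshold: float = 0.04
                      ) -> pd.DataFrame:
    """Re-check assigned parent-offspring links by opposing-homozygote rate.

    For every offspring-parent link, counts loci where both are genotyped
    and carry opposite homozygous dosages; links whose rate exceeds
    ``threshold`` are flagged.  Returns one row per link.
    """
    ids = set(map(str, g.samples))
    idx = {s: i for i, s in enumerate(g.samples)}
    d = g.dosages
    rows = []
    for r in pedigree.table.itertuples():
        for role, parent in (("sire", r.sire), ("dam", r.dam)):
            if parent == UNKNOWN:
                continue
            if r.id not in ids or parent not in ids:
                rows.append((r.id, parent, role, np.nan, 0, True))
                continue
            o, p = d[idx[r.id]], d[idx[parent]]
            ok = (o != MISSING) & (p != MISSING)
            n = int(ok.sum())
            opp = int((ok & (np.abs(o - p) == 2)).sum())
            rate = opp / n if n else float("nan")
            rows.append((r.id, parent, role, rate, n, (not n) or rate > threshold))
    return pd.DataFrame(
        rows, columns=["offspring_id", "parent_id", "role", "opposing_rate",
                       "n_compared", "flagged"]
    )
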