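"""Region-level comparative statistics of antibody interfaces.

Heavy- vs light-chain buried-surface dominance, paired comparisons of
CDR1+2 against CDR3 within the same V domain (BSA, IVW-IPL and ANSO, via
two-sided Wilcoxon signed-rank tests), and tidy CDR length-vs-BSA tables.

For ANSO, "CDR1 + 2" means the statistic computed on the pooled
CDR1 ∪ CDR2 interface-atom set (so that ANSO(CDR1∪CDR2)·|A₁∪A₂| =
IVW-IPL(CDR1) + IVW-IPL(CDR2)), not the sum of the two per-CDR ANSOs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METRICS = ("BSA", "IVW-IPL", "ANSO")
CHAINS = ("VH", "VL")


@dataclass
class WilcoxonResult:
    chain: str
    metric: str
    n_pairs: int            # non-tied pairs entering the test
    statistic: float
    p_value: float
    frac_v12_greater: float
    method: str


def paired_region_table(descriptor_rows: pd.DataFrame) -> pd.DataFrame:
    """Tidy (complex, chain, metric, v12, v3) table from a descriptor table.

    ``v12`` is value(CDR1)+value(CDR2) for BSA and IVW-IPL; for ANSO it is
    the pooled statistic (IVW-IPL₁+IVW-IPL₂)/(n₁+n₂).  Complexes whose
    CDR1∪CDR2 or CDR3 interface-atom set is empty are dropped for ANSO
    (undefined mean) and logged.
    """
    rows = []
    for _, r in descriptor_rows.iterrows():
        for chain in CHAINS:
            pre = chain + "_CDR"
            n1, n2, n3 = (r.get(f"{pre}{i}_n", 0) or 0 for i in (1, 2, 3))
            b1, b2, b3 = (r.get(f"{pre}{i}_bsa", 0.0) or 0.0 for i in (1, 2, 3))
            i1, i2, i3 = (r.get(f"{pre}{i}_ivw_ipl", 0.0) or 0.0 for i in (1, 2, 3))
            rows.append({"complex_id": r["complex_id"], "chain": chain,
                         "metric": "BSA", "v12": b1 + b2, "v3": b3})
            rows.append({"complex_id": r["complex_id"], "chain": chain,
                         "metric": "IVW-IPL", "v12": i1 + i2, "v3": i3})
            if (n1 + n2) > 0 and n3 > 0:
                rows.append({"complex_id": r["complex_id"], "chain": chain,
                             "metric": "ANSO",
                             "v12": (i1 + i2) / (n1 + n2), "v3": i3 / n3})
            else:
                logger.info("%s %s: empty CDR interface, ANSO pair dropped",
                            r["complex_id"], chain)
    return pd.DataFrame(rows)


def vh_vl_dominance(descriptor_rows: pd.DataFrame) -> float:
    """Fraction of complexes whose VH buried surface strictly exceeds VL's.

    Per-domain BSA sums the three CDR and four FR region contributions.
    """
    def dom_bsa(r, chain):
        total = 0.0
        for reg in ("CDR1", "CDR2", "CDR3", "FR1", "FR2", "FR3", "FR4"):
            total += r.get(f"{chain}_{reg}_bsa", 0.0) or 0.0
        return total

    wins = sum(dom_bsa(r, "VH") > dom_bsa(r, "VL")
               for _, r in descriptor_rows.iterrows())
    return wins / len(descriptor_rows)


def wilcoxon_signed_rank(v12, v3, exact_max_n: int = 25) -> tuple[float, float, int, str]:
    """Two-sided Wilcoxon signed-rank test of paired samples.

    Zero differences are dropped; the exact null distribution is used for
    n ≤ ``exact_max_n`` untied pairs, the normal approximation with
    continuity correction otherwise.  Returns (W, p, n_used, method).
    """
    d = np.asarray(v12, dtype=float) - np.asarray(v3, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all pairs tied: signed-rank test undefined")
    ties = len(np.unique(np.abs(d))) < n
    if n <= exact_max_n and not ties:
        method = "exact"
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        method = "approx"
        res = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=True)
    return float(res.statistic), float(res.pvalue), n, method


def paired_wilcoxon(table: pd.DataFrame) -> list[WilcoxonResult]:
    """Per (chain, metric) signed-rank comparison of CDR1+2 against CDR3.

    Reports the two-sided p-value together with the descriptive fraction
    of complexes where v12 > v3.  Requires ≥6 non-tied pairs for a
    meaningful p-value; smaller groups are skipped with a warning.
    """
    out = []
    for (chain, metric), grp in table.groupby(["chain", "metric"], sort=True):
        v12 = grp["v12"].to_numpy()
        v3 = grp["v3"].to_numpy()
        nz = int(np.sum(v12 != v3))
        if nz < 6:
            logger.warning("%s/%s: only %d non-tied pairs, test skipped",
                           chain, metric, nz)
            continue
        w, p, n, method = wilcoxon_signed_rank(v12, v3)
        out.append(WilcoxonResult(
            chain=chain, metric=metric, n_pairs=n, statistic=w, p_value=p,
            frac_v12_greater=float(np.mean(v12 > v3)), method=method))
    return out


def length_vs_bsa(descriptor_rows: pd.DataFrame,
                  region_lengths: pd.DataFrame) -> pd.DataFrame:
    """Tidy (complex, chain, region-group, length, bsa) table.

    ``region_lengths`` has columns complex_id, chain, region, length
    (residue counts within the IMGT limits).  CDR1 and CDR2 are reported
    as a pooled [CDR1·CDR2] group, CDR3 separately; one row per
    (complex, chain, region-group), no aggregation across complexes.
    """
    lengths = region_lengths.set_index(["complex_id", "chain", "region"])["length"]
    rows = []
    for _, r in descriptor_rows.iterrows():
        cid = r["complex_id"]
        for chain in CHAINS:
            try:
                l12 = int(lengths[(cid, chain, "CDR1")]) + int(lengths[(cid, chain, "CDR2")])
                l3 = int(lengths[(cid, chain, "CDR3")])
            except KeyError:
                continue
            b12 = (r.get(f"{chain}_CDR1_bsa", 0.0) or 0.0) + \
                  (r.get(f"{chain}_CDR2_bsa", 0.0) or 0.0)
            b3 = r.get(f"{chain}_CDR3_bsa", 0.0) or 0.0
            rows.append({"complex_id": cid, "chain": chain,
                         "region_group": "CDR1.CDR2", "length": l12, "bsa": b12})
            rows.append({"complex_id": cid, "chain": chain,
                         "region_group": "CDR3", "length": l3, "bsa": b3})
    return pd.DataFrame(rows)
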