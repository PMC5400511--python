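"""Independent straight-line oracles used by the test suite.

These deliberately avoid the package's own code paths (and scipy /
statsmodels / pandas): plain loops, dicts and math.comb over the files the
pipeline wrote, so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import csv
import math

import yaml


def read_counts(psm_path):
    """sample_id -> protein_id -> summed psm, straight off the TSV."""
    counts: dict[str, dict[str, int]] = {}
    with open(psm_path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            per = counts.setdefault(row["sample_id"], {})
            per[row["protein_id"]] = per.get(row["protein_id"], 0) + int(row["psm"])
    return counts


def curation_oracle(
    psm_path,
    design_path,
    threshold=2.0,
    pseudocount=0.5,
    min_count=2,
    null_min_count=2,
    inclusive=False,
):
    """Re-derive per-condition hits, null subtraction and reconciliation.

    Returns a dict with hit sets per condition (bait excluded), the union,
    the intersection, and the null-removed set.
    """
    counts = read_counts(psm_path)
    with open(design_path, encoding="utf-8") as fh:
        design = yaml.safe_load(fh)
    bait = design["bait"]

    def arm(genotype, condition, peptide):
        merged: dict[str, int] = {}
        for sid, spec in design["samples"].items():
            if spec["genotype"] != genotype or spec["peptide"] != peptide:
                continue
            if condition is not None and spec["condition"] != condition:
                continue
            for p, c in counts.get(sid, {}).items():
                merged[p] = merged.get(p, 0) + c
        return merged

    null_counts = arm("NULL", None, "minus")
    out = {}
    for cond in ("BCS", "CU"):
        a_counts = arm("WT", cond, "minus")
        b_counts = arm("WT", cond, "plus")
        hits = set()
        for p, a in a_counts.items():
            b = b_counts.get(p, 0)
            if b == 0 and a >= min_count:
                hits.add(p)
                continue
            ratio = (a + pseudocount) / (b + pseudocount)
            ok = ratio >= threshold if inclusive else ratio > threshold
            if ok:
                hits.add(p)
        hits = {p for p in hits if null_counts.get(p, 0) < null_min_count}
        hits.discard(bait)
        out[cond] = hits
    out["interactome"] = out["BCS"] | out["CU"]
    out["core"] = out["BCS"] & out["CU"]
    removed = set()
    for cond in ("BCS", "CU"):
        a_counts = arm("WT", cond, "minus")
        b_counts = arm("WT", cond, "plus")
        for p, a in a_counts.items():
            b = b_counts.get(p, 0)
            if b == 0 and a >= min_count:
                passed = True
            else:
                ratio = (a + pseudocount) / (b + pseudocount)
                passed = ratio >= threshold if inclusive else ratio > threshold
            if passed and null_counts.get(p, 0) >= null_min_count:
                removed.add(p)
    removed.discard(bait)
    out["null_removed"] = removed
    return out


def hypergeom_upper_tail(k, K, n, N):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def bh_stepup(pvals):
    """Benjamini-Hochberg q-values by the direct step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = min(running, 1.0)
    return q
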