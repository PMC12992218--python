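"""Brute-force reference scorer, independent of the scoring module.

Re-derives every coherence metric with plain loops over raw item triples,
working from the battery's exported item table rather than the package's
internal structures.  Used to cross-check ``score_participant``.
"""

from __future__ import annotations

import math


def brute_force_scores(values: dict[str, float], battery) -> dict[str, float]:
    """Recompute all coherence metrics for one participant from scratch."""
    table = battery.to_frame().to_dict(orient="records")

    marginals: dict[tuple[str, str], float] = {}
    for row in table:
        if row["kind"] == "marginal" and row["item_id"] in values:
            marginals[(row["candidate1"], row["state1"])] = values[row["item_id"]]

    # --- binary complementarity, state by state ---
    marg_devs = []
    for state in battery.states:
        if ("A", state) in marginals and ("B", state) in marginals:
            marg_devs.append(abs(marginals[("A", state)] + marginals[("B", state)] - 1.0))
    marginal_comp = sum(marg_devs) / len(marg_devs)

    # --- joint complementarity: 3 state pairs x 2 presentation orders ---
    config_sums: dict[tuple[tuple[str, str], bool], list[float]] = {}
    for row in table:
        if row["kind"] != "conjunction" or row["item_id"] not in values:
            continue
        pair = tuple(sorted([row["state1"], row["state2"]]))
        config_sums.setdefault((pair, bool(row["reversed"])), []).append(values[row["item_id"]])
    joint_devs = [abs(math.fsum(v) - 1.0) for v in config_sums.values() if len(v) == 4]
    joint_comp = sum(joint_devs) / len(joint_devs)

    # --- per-item fallacy scores ---
    cf_list, dcf_list, df_list, ddf_list = [], [], [], []
    for row in table:
        if row["kind"] not in ("conjunction", "disjunction"):
            continue
        key_a = (row["candidate1"], row["state1"])
        key_b = (row["candidate2"], row["state2"])
        if row["item_id"] not in values or key_a not in marginals or key_b not in marginals:
            continue
        pa, pb = marginals[key_a], marginals[key_b]
        v = values[row["item_id"]]
        if row["kind"] == "conjunction":
            cf = (v - pa if v > pa else 0.0) + (v - pb if v > pb else 0.0)
            bigger = pa if pa >= pb else pb
            dcf = v - bigger if v > bigger else 0.0
            cf_list.append(cf)
            dcf_list.append(dcf)
        else:
            df = (pa - v if pa > v else 0.0) + (pb - v if pb > v else 0.0)
            smaller = pa if pa <= pb else pb
            ddf = smaller - v if smaller > v else 0.0
            df_list.append(df)
            ddf_list.append(ddf)

    def mean(xs):
        return sum(xs) / len(xs)

    def prevalence(xs):
        return sum(1 for x in xs if x > 0) / len(xs)

    return {
        "marginal_comp": marginal_comp,
        "joint_comp": joint_comp,
        "cf_mean": mean(cf_list),
        "dcf_mean": mean(dcf_list),
        "df_mean": mean(df_list),
        "ddf_mean": mean(ddf_list),
        "cf_prevalence": prevalence(cf_list),
        "dcf_prevalence": prevalence(dcf_list),
        "df_prevalence": prevalence(df_list),
        "ddf_prevalence": prevalence(ddf_list),
    }
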