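"""Per-scan summaries of the effective connectome.

Global, within-network, and between-network EC averages (overall and
split into excitatory/positive and inhibitory/negative parts), the
network segregation index NSI = (EC_W - EC_B) / EC_W, the network
integration index NII = |between-network excitatory EC| +
|between-network inhibitory EC|, and nodal/network EC strength (ECS,
the row sum of incoming EC).

Self-connections are excluded from every mean and sum by default: the
diagonal holds self-decay terms, not inter-regional connectivity.  Pass
``include_diagonal=True`` for the literal all-entries reading.  Sign
subsets are strict (> 0 / < 0); exact zeros belong to neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lifespan_ec.io import ECMatrix, Parcellation


def _masked_mean(values: np.ndarray, mask: np.ndarray) -> tuple[float, bool]:
    """Mean over a boolean mask; (0.0, True-flag) when the subset is empty."""
    if not mask.any():
        return 0.0, True
    return float(values[mask].mean()), False


def global_means(ec: ECMatrix, include_diagonal: bool = False) -> dict:
    """Whole-brain mean EC plus excitatory/inhibitory means.

    Returns a dict with keys overall, exc, inh and empty-subset flags
    exc_empty/inh_empty (a flagged component is reported as 0).
    """
    v = ec.values
    include = np.ones_like(v, dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(include, False)
    overall = float(v[include].mean())
    exc, exc_empty = _masked_mean(v, include & (v > 0))
    inh, inh_empty = _masked_mean(v, include & (v < 0))
    return {
        "overall": overall, "exc": exc, "inh": inh,
        "exc_empty": exc_empty, "inh_empty": inh_empty,
    }


def network_ec(
    ec: ECMatrix, parcellation: Parcellation, include_diagonal: bool = False
) -> pd.DataFrame:
    """Within- and between-network EC per network.

    within(n): mean over ordered pairs (target, source), target != source,
    both in n.  between(n): mean over pairs with exactly one endpoint in
    n, both directions pooled; incoming(n) restricts to target in n,
    outgoing(n) to source in n.  Each average also has exc/inh variants
    restricted to positive/negative entries.  A network with fewer than
    two regions has no within value (NaN, flagged).
    """
    v = ec.values
    member = parcellation.membership()
    rows = []
    for ni, net in enumerate(parcellation.networks):
        in_n = member == ni
        pair_in = np.outer(in_n, in_n)
        if not include_diagonal:
            np.fill_diagonal(pair_in, False)
        incoming_mask = np.outer(in_n, ~in_n)   # target in n, source outside
        outgoing_mask = np.outer(~in_n, in_n)   # source in n, target outside
        between_mask = incoming_mask | outgoing_mask

        row: dict = {"network": net, "n_regions": int(in_n.sum())}
        row["within_flagged"] = in_n.sum() < 2
        for label, mask in (
            ("within", pair_in),
            ("between", between_mask),
            ("incoming", incoming_mask),
            ("outgoing", outgoing_mask),
        ):
            val, empty = _masked_mean(v, mask)
            row[label] = np.nan if (label == "within" and row["within_flagged"]) else val
            exc, exc_empty = _masked_mean(v, mask & (v > 0))
            inh, inh_empty = _masked_mean(v, mask & (v < 0))
            row[f"{label}_exc"] = exc
            row[f"{label}_inh"] = inh
            row[f"{label}_exc_empty"] = exc_empty
            row[f"{label}_inh_empty"] = inh_empty
        rows.append(row)
    return pd.DataFrame(rows).set_index("network")


def segregation_integration(network_table: pd.DataFrame) -> pd.DataFrame:
    """NSI and raw NII per network, plus the across-network means.

    NSI(n) = (within - between) / within; undefined (NaN) where within
    is 0 or missing.  The mean NSI uses the mean within and mean between
    values, not the mean of the per-network ratios.  Raw NII(n) =
    |between_exc| + |between_inh|; normalization by the maximal NII of
    the analysis set is left to :func:`normalize_nii` so the caller
    controls the scope of the maximum.  The mean NII is the average of
    the per-network raw values.
    """
    out = network_table[["within", "between"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["nsi"] = (out["within"] - out["between"]) / out["within"]
    out.loc[out["within"] == 0, "nsi"] = np.nan
    out["nii_raw"] = network_table["between_exc"].abs() + network_table["between_inh"].abs()

    mean_within = out["within"].mean()
    mean_between = out["between"].mean()
    mean_nsi = np.nan if mean_within == 0 else (mean_within - mean_between) / mean_within
    out.attrs["mean_nsi"] = float(mean_nsi)
    out.attrs["mean_nii_raw"] = float(out["nii_raw"].mean())
    return out


def normalize_nii(nii_values: np.ndarray) -> np.ndarray:
    """Scale NII values by the maximum over the supplied analysis set."""
    nii_values = np.asarray(nii_values, dtype=float)
    top = np.nanmax(np.abs(nii_values)) if nii_values.size else 0.0
    if top == 0:
        return nii_values
    return nii_values / top


def nodal_strengths(
    ec: ECMatrix, parcellation: Parcellation | None = None, include_diagonal: bool = False
) -> pd.DataFrame:
    """Nodal EC strength: the sum of incoming EC to each region.

    ECS_i is the i-th row sum of the EC matrix (excitatory/inhibitory
    variants sum only positive/negative entries; overall = exc + inh).
    When a parcellation is given, network ECS (mean nodal ECS per
    network) and its across-network mean are attached as attrs.
    """
    v = ec.values.copy()
    if not include_diagonal:
        np.fill_diagonal(v, 0.0)
    pos = np.where(v > 0, v, 0.0)
    neg = np.where(v < 0, v, 0.0)
    df = pd.DataFrame(
        {
            "region": list(ec.region_ids),
            "ecs": v.sum(axis=1),
            "ecs_exc": pos.sum(axis=1),
            "ecs_inh": neg.sum(axis=1),
        }
    ).set_index("region")
    if parcellation is not None:
        df["network"] = [parcellation.network_of[r] for r in df.index]
        net = df.groupby("network", sort=False)[["ecs", "ecs_exc", "ecs_inh"]].mean()
        net = net.loc[[n for n in parcellation.networks if n in net.index]]
        df.attrs["network_ecs"] = net
        df.attrs["mean_network_ecs"] = net["ecs"].mean()
    return df


@dataclass
class ScanMetrics:
    """All per-scan metrics of one EC matrix, with scan metadata."""

    subject_id: str
    age: float
    sex: int
    site: str
    global_metrics: dict
    network_table: pd.DataFrame
    seg_int: pd.DataFrame
    nodal: pd.DataFrame

    def long_rows(self) -> list[dict]:
        """Scan metrics as long-format rows (one row per metric)."""
        meta = {
            "subject_id": self.subject_id, "age": self.age,
            "sex": self.sex, "site": self.site,
        }
        rows = [
            {**meta, "metric": "global_ec", "network": "", "value": self.global_metrics["overall"]},
            {**meta, "metric": "global_ec_exc", "network": "", "value": self.global_metrics["exc"]},
            {**meta, "metric": "global_ec_inh", "network": "", "value": self.global_metrics["inh"]},
            {**meta, "metric": "mean_within_ec", "network": "", "value": self.network_table["within"].mean()},
            {**meta, "metric": "mean_between_ec", "network": "", "value": self.network_table["between"].mean()},
            {**meta, "metric": "mean_nsi", "network": "", "value": self.seg_int.attrs["mean_nsi"]},
            {**meta, "metric": "mean_nii", "network": "", "value": self.seg_int.attrs["mean_nii_raw"]},
            {**meta, "metric": "mean_network_ecs", "network": "",
             "value": self.nodal.attrs.get("mean_network_ecs", np.nan)},
        ]
        for net, r in self.network_table.iterrows():
            for col in ("within", "between", "incoming", "outgoing",
                        "within_exc", "within_inh", "between_exc", "between_inh",
                        "incoming_exc", "incoming_inh", "outgoing_exc", "outgoing_inh"):
                rows.append({**meta, "metric": f"net_{col}", "network": net, "value": r[col]})
        for net, r in self.seg_int.iterrows():
            rows.append({**meta, "metric": "nsi", "network": net, "value": r["nsi"]})
            rows.append({**meta, "metric": "nii_raw", "network": net, "value": r["nii_raw"]})
        net_ecs = self.nodal.attrs.get("network_ecs")
        if net_ecs is not None:
            for net, r in net_ecs.iterrows():
                rows.append({**meta, "metric": "network_ecs", "network": net, "value": r["ecs"]})
        return rows


def scan_metrics(
    ec: ECMatrix,
    parcellation: Parcellation,
    subject_id: str = "",
    age: float = np.nan,
    sex: int = 0,
    site: str = "",
    include_diagonal: bool = False,
) -> ScanMetrics:
    """Compute every per-scan summary for one EC matrix."""
    net_table = network_ec(ec, parcellation, include_diagonal)
    return ScanMetrics(
        subject_id=subject_id, age=age, sex=sex, site=site,
        global_metrics=global_means(ec, include_diagonal),
        network_table=net_table,
        seg_int=segregation_integration(net_table),
        nodal=nodal_strengths(ec, parcellation, include_diagonal),
    )


def metrics_table(scans: list[ScanMetrics]) -> pd.DataFrame:
    """Long-format table (one row per scan x metric) for trajectory fitting."""
    rows: list[dict] = []
    for sm in scans:
        rows.extend(sm.long_rows())
    return pd.DataFrame(rows)


def nodal_table(scans: list[ScanMetrics]) -> pd.DataFrame:
    """Per-region ECS long table across scans (overall/exc/inh)."""
    rows = []
    for sm in scans:
        for region, r in sm.nodal.iterrows():
            rows.append(
                {
                    "subject_id": sm.subject_id, "age": sm.age, "sex": sm.sex,
                    "site": sm.site, "region": region,
                    "ecs": r["ecs"], "ecs_exc": r["ecs_exc"], "ecs_inh": r["ecs_inh"],
                }
            )
    return pd.DataFrame(rows)
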