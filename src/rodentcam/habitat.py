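"""Site-level habitat covariates.

Three classes of covariates, each computed from a field survey table:

* seabird burrow density from the point-centre-quarter (PCQ) method — the
  distance to the nearest burrow in each of four quadrants (NE, NW, SE,
  SW) around the camera, to a maximum of 40 m;
* structural complexity from a 1-m structure pole read at eight points per
  site: vegetation touches per 100-mm height band (0-10 each), summarised
  as the mean summed touches over a height band of interest (near-ground
  complexity = 100-400 mm);
* floristic composition: visually estimated percent covers of the four
  dominant plant species plus 'other', and overstorey cover above 1 m.

The default PCQ density estimator is the classic point-centre-quarter form
D = 1/mu^2 (mu = mean of the four quadrant distances in metres, density
converted to burrows/ha).  With only four distances per site this
estimator carries a known upward bias of order +20-25%; the unbiased
Pollard form 4(4n-1)/(pi * sum d^2) is available via ``method="pollard"``,
and ``pooled_pcq_density`` gives the consistent survey-level estimate that
pools distances across sites.  Quadrants with no burrow within the
truncation radius contribute the truncation distance to mu (conservative:
biases density downward); sites with no burrow in any quadrant are
assigned density zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

M2_PER_HA = 1e4
COVARIATE_COLUMNS = (
    "Poa", "Tetra", "Rhag", "Disphyma", "Other",
    "C10_40", "C_gt1m", "Atden", "Emden", "BD",
)
DEFAULT_BAND = (100, 400)  # mm, near-ground complexity


def pcq_density(
    distances, truncation: float = 40.0, method: str = "cottam"
) -> float:
    """Burrow density (per hectare) from four quadrant distances (metres).

    ``distances`` holds one value per quadrant; NaN means no burrow within
    the truncation radius.  All-empty sites return 0.  A recorded distance
    of zero is invalid (a burrow cannot sit at the camera point).
    """
    d = np.asarray(distances, dtype=float)
    if d.shape != (4,):
        raise ValueError(f"expected 4 quadrant distances, got shape {d.shape}")
    present = ~np.isnan(d)
    if not present.any():
        return 0.0
    if np.any(d[present] <= 0.0):
        raise ValueError("quadrant distances must be positive")
    if np.any(d[present] > truncation):
        raise ValueError(
            f"distance exceeds the {truncation} m truncation radius"
        )
    d_full = np.where(present, d, truncation)
    if method == "cottam":
        mu = d_full.mean()
        return float(M2_PER_HA / mu**2)
    if method == "pollard":
        return float(M2_PER_HA * 12.0 / (np.pi * (d_full**2).sum()))
    raise ValueError(f"unknown PCQ method {method!r}")


def pooled_pcq_density(
    pcq: pd.DataFrame, truncation: float = 40.0
) -> float:
    """Survey-level PCQ density (per ha) pooling distances across sites.

    D = 1/mu^2 with mu the mean over every quadrant distance in the survey
    (truncation distance substituted for empty quadrants).  Unlike the
    per-site estimate this is consistent as the number of sites grows.
    """
    d = pcq["distance_m"].to_numpy(dtype=float)
    if d.size == 0:
        raise ValueError("no PCQ distances supplied")
    d = np.where(np.isnan(d), truncation, d)
    if np.any(d <= 0):
        raise ValueError("quadrant distances must be positive")
    mu = d.mean()
    return float(M2_PER_HA / mu**2)


def pcq_density_table(
    pcq: pd.DataFrame, truncation: float = 40.0, method: str = "cottam"
) -> pd.DataFrame:
    """Per-site burrow densities by type from a long PCQ table.

    Input columns: site_id, quadrant, distance_m (NaN = none within range),
    burrow_type ('penguin' | 'shearwater').  Output columns: site_id,
    Atden (shearwater burrows/ha), Emden (penguin burrows/ha), BD (their
    sum), and ``truncated_quadrants`` flagging sites where the truncation
    substitution was applied.
    """
    required = {"site_id", "quadrant", "distance_m", "burrow_type"}
    missing = required - set(pcq.columns)
    if missing:
        raise ValueError(f"PCQ table lacks columns {sorted(missing)}")
    col_for_type = {"shearwater": "Atden", "penguin": "Emden"}
    sites = pd.unique(pcq["site_id"])
    out = pd.DataFrame({"site_id": sites}).set_index("site_id")
    out["Atden"] = 0.0
    out["Emden"] = 0.0
    out["truncated_quadrants"] = 0
    for (site, btype), grp in pcq.groupby(["site_id", "burrow_type"], sort=False):
        if btype not in col_for_type:
            raise ValueError(f"unknown burrow type {btype!r}")
        d = grp["distance_m"].to_numpy(dtype=float)
        if d.size != 4:
            raise ValueError(
                f"site {site} has {d.size} {btype} quadrant rows, expected 4"
            )
        dens = pcq_density(d, truncation=truncation, method=method)
        out.loc[site, col_for_type[btype]] = dens
        n_nan = int(np.isnan(d).sum())
        if 0 < n_nan < 4:
            out.loc[site, "truncated_quadrants"] += n_nan
    out["BD"] = out["Atden"] + out["Emden"]
    return out.reset_index()


def structural_complexity(
    poles: pd.DataFrame, band: tuple[int, int] = DEFAULT_BAND
) -> pd.Series:
    """Mean (over the 8 poles) of summed vegetation touches within a height
    band, per site.

    ``poles`` is long-form (site_id, pole, band, touches) with band index b
    covering heights [100(b-1), 100b) mm.  ``band`` is a (low, high) height
    range in mm aligned to 100-mm intervals within 0-1000.
    """
    lo, hi = band
    if lo % 100 or hi % 100 or not (0 <= lo < hi <= 1000):
        raise ValueError(
            f"band must be 100-mm aligned within 0-1000 mm, got {band}"
        )
    band_idx = range(lo // 100 + 1, hi // 100 + 1)
    required = {"site_id", "pole", "band", "touches"}
    missing = required - set(poles.columns)
    if missing:
        raise ValueError(f"pole table lacks columns {sorted(missing)}")
    counts = poles.groupby("site_id")["pole"].nunique()
    if (counts != 8).any():
        bad = counts.index[counts != 8].tolist()
        raise ValueError(f"sites without exactly 8 poles: {bad}")
    sel = poles[poles["band"].isin(band_idx)]
    per_pole = sel.groupby(["site_id", "pole"])["touches"].sum()
    return per_pole.groupby("site_id").mean().rename("complexity")


def assemble_covariates(
    pcq: pd.DataFrame,
    poles: pd.DataFrame,
    covers: pd.DataFrame,
    truncation: float = 40.0,
    pcq_method: str = "cottam",
    band: tuple[int, int] = DEFAULT_BAND,
    standardize: bool = False,
) -> pd.DataFrame:
    """One covariate row per site: covers, C10_40, C_gt1m, Atden, Emden, BD.

    Sites are outer-joined across the three survey tables; a site missing
    one survey gets NaN in the affected columns and a logged warning.
    Covariates are left on their raw scales by default; ``standardize``
    z-scores the numeric columns and records means/sds in ``attrs``.
    """
    if covers["site_id"].duplicated().any():
        dup = covers.loc[covers["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate cover rows for sites {dup}")
    cover_cols = [c for c in ("Poa", "Tetra", "Rhag", "Disphyma", "Other")
                  if c in covers.columns]
    total = covers[cover_cols].sum(axis=1)
    if (total > 100.5).any():
        bad = covers.loc[total > 100.5, "site_id"].tolist()
        raise ValueError(f"percent covers exceed 100 at sites {bad}")

    dens = pcq_density_table(pcq, truncation=truncation, method=pcq_method)
    comp = structural_complexity(poles, band=band).rename("C10_40")
    out = covers.merge(comp, on="site_id", how="outer")
    out = out.merge(
        dens[["site_id", "Atden", "Emden", "BD"]], on="site_id", how="outer"
    )
    for col in ("C10_40", "Atden", "C_gt1m"):
        if col in out.columns and out[col].isna().any():
            n = int(out[col].isna().sum())
            logger.warning("%d sites missing %s after outer join", n, col)
    out.attrs["pcq_method"] = pcq_method
    out.attrs["pcq_empty_quadrant_rule"] = "truncation distance substituted"
    if standardize:
        num = [c for c in COVARIATE_COLUMNS if c in out.columns]
        means = out[num].mean()
        sds = out[num].std(ddof=0)
        out[num] = (out[num] - means) / sds.replace(0.0, 1.0)
        out.attrs["standardized"] = True
        out.attrs["means"] = means.to_dict()
        out.attrs["sds"] = sds.to_dict()
    else:
        out.attrs["standardized"] = False
    return out


def correlation_screen(
    covariates: pd.DataFrame, threshold: float = 0.55
) -> tuple[float, pd.DataFrame]:
    """Pairwise collinearity screen over the assembled covariates.

    Returns the maximum absolute pairwise Pearson correlation and a table
    of pairs whose |r| exceeds the threshold (candidate models should not
    combine such pairs).
    """
    num = covariates[[c for c in COVARIATE_COLUMNS if c in covariates.columns]]
    corr = num.corr()
    pairs = []
    cols = corr.columns
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if np.isfinite(r):
                pairs.append((cols[i], cols[j], float(r)))
    table = pd.DataFrame(pairs, columns=["var1", "var2", "r"])
    max_r = float(table["r"].abs().max()) if len(table) else 0.0
    flagged = table[table["r"].abs() > threshold].reset_index(drop=True)
    return max_r, flagged
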