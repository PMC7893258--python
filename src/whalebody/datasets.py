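"""Bundled study data.

``load_tagged_whales`` returns the published per-whale comparison table for
the 21 tagged humpbacks that were also photographed from the air: tissue
body density posterior (mean, sd) from the hydrodynamic glide fit, the
combined drag term, and LSSAI from the best overhead frame, together with
date, location, age class and sex.  This is the cross-validation dataset
linking the two body-condition channels.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fusion import WhaleRecord, season_day


def load_tagged_whales() -> pd.DataFrame:
    """The 21-whale tag-vs-photogrammetry comparison table."""
    with resources.files("whalebody.data").joinpath("tagged_whales.csv").open() as fh:
        return pd.read_csv(fh, dtype={"uav_id": str, "whale_id": str})


_SEX = {"F": "female", "M": "male", "U": "unknown"}


def tagged_whale_records() -> list[WhaleRecord]:
    """The comparison table as dual-channel :class:`WhaleRecord` objects."""
    df = load_tagged_whales()
    records = []
    for r in df.itertuples(index=False):
        age = str(r.age_class)
        records.append(
            WhaleRecord(
                whale_id=str(r.tag_id),
                location=str(r.location),
                season_day=season_day(str(r.date_iso)),
                sex=_SEX[str(r.sex)],
                pregnant="pregnant" in age,
                lactating="lactating" in age,
                immature="juvenile" in age,
                tbd_obs=[(float(r.rho_mean), float(r.rho_sd))],
                lssai_obs=float(r.lssai),
            )
        )
    return records
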