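"""Packaged reference tables."""

from importlib import resources

import pandas as pd


def load_reference_fish_summary() -> pd.DataFrame:
    """Published per-fish summary of the Gullmar Fjord cod deployment.

    The 39 retained fish of the 2015/2016 two-site study: release site and
    date, size at tagging, days detected and monitored, and the reported
    residency and movement indices (both rounded to 2 decimals in the
    source).  Used as the worked-example input for the residency-index
    arithmetic.
    """
    with resources.files("codnet.data").joinpath("gullmar_fish_summary.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"transmitter_id": str, "release_site": str})
    df["release_date"] = pd.to_datetime(df["release_date"]).dt.date
    return df
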