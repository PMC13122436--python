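"""Published per-year sampling-point summaries for the American River study.

Annual summary statistics of natal-exit size, early-migrant percentage (at
the 47 mm study cutoff and the legacy 55 mm cutoff) and freshwater-exit
size for American-River-assigned fall-run Chinook at the four sampling
regions, together with mean Jan–June natal-river flow.  These published
values serve as reference inputs for the all-years aggregation rules and
for cross-study comparison; they are data, not computed here.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["sampling_point_summaries"]

_TABLE = """\
region,outmigration_year,flow_cfs,n,natal_mean_mm,natal_sd_mm,pct_early_47,pct_early_55,fw_mean_mm,fw_sd_mm
delta_entry,2014,981,100,45.0,12.4,73.0,85.0,,
delta_entry,2015,1133,100,38.9,8.6,95.0,95.0,,
delta_entry,2016,4240,28,44.6,13.5,67.9,78.6,,
delta_entry,2017,15264,10,41.6,10.7,70.0,90.0,,
delta_entry,2018,3998,40,42.7,13.6,80.0,87.5,,
delta_bay,2014,981,7,41.9,11.6,71.4,85.7,,
delta_bay,2015,1133,5,50.4,13.2,40.0,80.0,,
delta_bay,2016,4240,105,37.6,4.9,93.3,100.0,,
delta_bay,2017,15264,38,36.4,2.4,97.4,100.0,,
delta_bay,2018,3998,54,36.9,4.3,98.1,98.1,,
delta_exit,2014,981,5,56.0,12.9,20.0,60.0,73.2,2.2
delta_exit,2015,1133,6,63.5,16.3,16.7,33.3,73.3,17.5
delta_exit,2016,4240,26,53.9,18.0,46.2,57.7,81.3,7.9
delta_exit,2017,15264,15,66.4,11.2,6.7,13.3,84.5,6.4
delta_exit,2018,3998,9,55.3,18.6,44.4,44.4,78.9,5.6
delta_exit,2019,7977,50,62.3,15.7,22.0,26.0,79.4,13.2
spawning,2011,8053,67,62.8,14.3,19.4,23.9,75.0,6.7
spawning,2012,2276,319,75.7,14.1,6.6,9.7,81.8,8.9
spawning,2013,1900,311,68.9,17.6,16.1,23.2,78.6,9.1
spawning,2014,981,115,81.4,16.1,7.0,10.4,85.6,8.6
spawning,2015,1133,89,79.4,12.2,3.4,10.1,81.9,8.5
spawning,2016,4240,21,55.5,18.3,47.6,52.4,77.7,9.2
spawning,2017,15264,58,70.5,10.9,1.7,13.8,76.5,9.3
spawning,2018,3998,31,63.7,13.6,12.9,25.8,75.8,7.2
spawning,2019,7977,42,62.5,17.0,23.8,33.3,76.9,9.1
"""


def sampling_point_summaries() -> pd.DataFrame:
    """Published annual summaries by sampling region (one row per region-year)."""
    return pd.read_csv(StringIO(_TABLE))
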