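"""Published Guinea survey estimates bundled for worked examples and checks.

These are the disaggregated skilled-birth-attendance (SBA) coverage and
neonatal-mortality-rate (NMR) estimates for the Guinea DHS 1999/2005/2012 and
MICS 2016 surveys as published through the WHO Health Equity Assessment
Toolkit (HEAT), together with the published summary measures (D, R, PAR, PAF)
computed from them.  The raw microdata are not redistributable; these printed
estimates let users exercise the summary-measure operations on real numbers
and serve as fixed inputs for the package's desk checks.

Conventions: SBA on the percent scale, NMR per 1000 live births; ``pop_n`` is
the unweighted denominator; intervals are 95% uncertainty intervals.  Guinea
used five survey domains in 1999 and eight regions from 2005 onward, so the
region subgroups differ across surveys.
"""

from __future__ import annotations

import pandas as pd

# (dimension, subgroup, year, estimate, ui_low, ui_high, pop_n)
_SBA_ROWS = [
    ("wealth_quintile", "Q1", 1999, 12.4, 9.3, 16.4, 801),
    ("wealth_quintile", "Q1", 2005, 15.2, 10.6, 21.3, 955),
    ("wealth_quintile", "Q1", 2012, 18.9, 14.6, 24.2, 945),
    ("wealth_quintile", "Q1", 2016, 27.0, 22.5, 32.1, 567),
    ("wealth_quintile", "Q2", 1999, 16.0, 12.5, 20.3, 727),
    ("wealth_quintile", "Q2", 2005, 20.0, 16.7, 23.8, 857),
    ("wealth_quintile", "Q2", 2012, 28.4, 23.8, 33.4, 907),
    ("wealth_quintile", "Q2", 2016, 49.0, 42.7, 55.3, 620),
    ("wealth_quintile", "Q3", 1999, 27.1, 22.9, 31.8, 691),
    ("wealth_quintile", "Q3", 2005, 34.8, 29.1, 41.1, 825),
    ("wealth_quintile", "Q3", 2012, 39.0, 33.0, 45.4, 880),
    ("wealth_quintile", "Q3", 2016, 60.6, 54.3, 66.6, 570),
    ("wealth_quintile", "Q4", 1999, 55.3, 49.3, 61.1, 658),
    ("wealth_quintile", "Q4", 2005, 57.5, 52.7, 62.2, 725),
    ("wealth_quintile", "Q4", 2012, 67.7, 62.7, 72.4, 824),
    ("wealth_quintile", "Q4", 2016, 87.3, 83.1, 90.5, 564),
    ("wealth_quintile", "Q5", 1999, 84.1, 80.6, 87.1, 547),
    ("wealth_quintile", "Q5", 2005, 86.8, 82.5, 90.2, 598),
    ("wealth_quintile", "Q5", 2012, 91.9, 88.0, 94.5, 679),
    ("wealth_quintile", "Q5", 2016, 95.6, 92.9, 97.3, 456),
    ("education", "none", 1999, 30.1, 27.1, 33.2, 2941),
    ("education", "none", 2005, 33.3, 29.9, 36.9, 3421),
    ("education", "none", 2012, 38.1, 34.3, 42.1, 3243),
    ("education", "none", 2016, 53.3, 49.7, 56.9, 1949),
    ("education", "primary", 1999, 60.4, 53.3, 67.2, 287),
    ("education", "primary", 2005, 67.9, 61.8, 73.5, 340),
    ("education", "primary", 2012, 64.3, 58.9, 69.4, 546),
    ("education", "primary", 2016, 73.2, 67.5, 78.2, 392),
    ("education", "secondary+", 1999, 85.4, 78.8, 90.2, 198),
    ("education", "secondary+", 2005, 85.3, 78.7, 90.0, 199),
    ("education", "secondary+", 2012, 83.4, 78.1, 87.7, 447),
    ("education", "secondary+", 2016, 92.5, 88.4, 95.2, 438),
    ("residence", "rural", 1999, 21.9, 18.8, 25.22, 2558),
    ("residence", "rural", 2005, 26.0, 22.5, 29.9, 3048),
    ("residence", "rural", 2012, 32.0, 27.5, 36.9, 3085),
    ("residence", "rural", 2016, 46.1, 42.1, 50.2, 1823),
    ("residence", "urban", 1999, 77.1, 72.6, 81.0, 867),
    ("residence", "urban", 2005, 81.8, 77.3, 85.5, 913),
    ("residence", "urban", 2012, 84.5, 81.2, 87.3, 1152),
    ("residence", "urban", 2016, 93.2, 90.4, 95.1, 956),
    ("region", "Lower Guinea", 1999, 31.8, 25.2, 39.1, 703),
    ("region", "Central Guinea", 1999, 18.5, 15.0, 22.6, 711),
    ("region", "Upper Guinea", 1999, 20.7, 15.7, 26.7, 663),
    ("region", "Forest Guinea", 1999, 39.0, 32.4, 46.0, 909),
    ("region", "Conakry", 1999, 87.1, 83.0, 90.3, 437),
    ("region", "Boke", 2005, 26.4, 20.5, 33.4, 454),
    ("region", "Boke", 2012, 42.9, 33.2, 53.2, 392),
    ("region", "Boke", 2016, 71.6, 62.9, 78.8, 326),
    ("region", "Conakry", 2005, 90.1, 85.1, 93.6, 422),
    ("region", "Conakry", 2012, 90.1, 85.4, 93.4, 626),
    ("region", "Conakry", 2016, 95.6, 92.3, 97.5, 494),
    ("region", "Faranah", 2005, 33.5, 26.4, 41.6, 339),
    ("region", "Faranah", 2012, 29.8, 22.4, 38.5, 436),
    ("region", "Faranah", 2016, 46.5, 36.8, 56.4, 239),
    ("region", "Kankan", 2005, 41.1, 32.7, 50.2, 616),
    ("region", "Kankan", 2012, 45.0, 34.8, 55.6, 783),
    ("region", "Kankan", 2016, 53.2, 45.9, 60.4, 549),
    ("region", "Kindia", 2005, 28.2, 22.0, 35.3, 563),
    ("region", "Kindia", 2012, 41.8, 31.9, 52.4, 597),
    ("region", "Kindia", 2016, 64.4, 57.3, 70.8, 361),
    ("region", "Labe", 2005, 18.8, 14.1, 24.5, 391),
    ("region", "Labe", 2012, 32.2, 24.6, 40.9, 385),
    ("region", "Labe", 2016, 45.6, 34.8, 56.8, 219),
    ("region", "Mamou", 2005, 18.9, 13.6, 25.7, 263),
    ("region", "Mamou", 2012, 19.6, 14.8, 25.5, 275),
    ("region", "Mamou", 2016, 30.3, 22.8, 38.8, 218),
    ("region", "Nzerekore", 2005, 42.8, 32.7, 53.6, 911),
    ("region", "Nzerekore", 2012, 43.0, 32.3, 54.5, 741),
    ("region", "Nzerekore", 2016, 60.2, 48.7, 70.7, 370),
]

#: National SBA coverage (%) per survey.
SBA_NATIONAL = {1999: 35.8, 2005: 38.9, 2012: 46.3, 2016: 62.3}

_NMR_ROWS = [
    ("wealth_quintile", "Q1", 1999, 56.1, 47.1, 66.7, 2941),
    ("wealth_quintile", "Q1", 2005, 60.0, 48.9, 73.3, 3238),
    ("wealth_quintile", "Q1", 2012, 49.0, 39.8, 60.1, 3190),
    ("wealth_quintile", "Q2", 1999, 57.9, 47.2, 70.9, 2529),
    ("wealth_quintile", "Q2", 2005, 60.9, 51.9, 71.3, 2851),
    ("wealth_quintile", "Q2", 2012, 37.1, 28.7, 47.7, 3125),
    ("wealth_quintile", "Q3", 1999, 54.1, 44.8, 65.1, 2369),
    ("wealth_quintile", "Q3", 2005, 61.3, 51.8, 72.3, 2820),
    ("wealth_quintile", "Q3", 2012, 40.5, 33.2, 49.5, 2949),
    ("wealth_quintile", "Q4", 1999, 48.6, 39.8, 59.3, 2304),
    ("wealth_quintile", "Q4", 2005, 46.6, 38.2, 56.8, 2469),
    ("wealth_quintile", "Q4", 2012, 40.4, 30.4, 53.5, 2642),
    ("wealth_quintile", "Q5", 1999, 38.5, 30.2, 48.9, 1944),
    ("wealth_quintile", "Q5", 2005, 38.2, 27.3, 53.2, 1957),
    ("wealth_quintile", "Q5", 2012, 31.7, 22.7, 44.3, 2017),
    ("education", "none", 1999, 54.6, 49.1, 60.6, 10516),
    ("education", "none", 2005, 55.7, 50.4, 61.4, 11703),
    ("education", "none", 2012, 41.6, 36.6, 47.2, 11348),
    ("education", "primary", 1999, 40.4, 27.6, 58.6, 870),
    ("education", "primary", 2005, 52.2, 38.5, 70.4, 1017),
    ("education", "primary", 2012, 43.5, 29.1, 64.4, 1489),
    ("education", "secondary+", 1999, 24.9, 15.0, 41.1, 702),
    ("education", "secondary+", 2005, 42.1, 25.6, 68.5, 616),
    ("education", "secondary+", 2012, 23.6, 15.2, 36.4, 1085),
    ("residence", "rural", 1999, 55.3, 49.1, 62.1, 9072),
    ("residence", "rural", 2005, 57.4, 52.1, 63.4, 10302),
    ("residence", "rural", 2012, 41.9, 36.5, 48.1, 10443),
    ("residence", "urban", 1999, 41.5, 34.8, 49.4, 3017),
    ("residence", "urban", 2005, 45.7, 36.8, 56.5, 3034),
    ("residence", "urban", 2012, 35.8, 28.2, 45.3, 3479),
    ("child_sex", "female", 1999, 44.0, 38.2, 50.6, 5865),
    ("child_sex", "female", 2005, 45.8, 39.8, 52.8, 6464),
    ("child_sex", "female", 2012, 34.2, 28.7, 40.7, 6816),
    ("child_sex", "male", 1999, 59.2, 52.7, 66.5, 6224),
    ("child_sex", "male", 2005, 63.2, 56.2, 70.9, 6872),
    ("child_sex", "male", 2012, 46.3, 40.2, 53.3, 7107),
    ("region", "Lower Guinea", 1999, 44.9, 35.8, 56.2, 2557),
    ("region", "Central Guinea", 1999, 47.4, 37.7, 59.5, 2760),
    ("region", "Upper Guinea", 1999, 61.7, 51.1, 74.5, 2227),
    ("region", "Forest Guinea", 1999, 58.8, 47.3, 72.8, 3020),
    ("region", "Conakry", 1999, 43.1, 34.2, 54.2, 1524),
    ("region", "Boke", 2005, 46.7, 36.6, 59.3, 1586),
    ("region", "Boke", 2012, 43.0, 29.2, 62.8, 1322),
    ("region", "Conakry", 2005, 37.0, 24.0, 56.4, 1345),
    ("region", "Conakry", 2012, 32.8, 21.9, 48.8, 1798),
    ("region", "Faranah", 2005, 72.4, 56.7, 91.9, 1136),
    ("region", "Faranah", 2012, 44.6, 31.1, 63.7, 1478),
    ("region", "Kankan", 2005, 49.7, 41.8, 59.1, 2005),
    ("region", "Kankan", 2012, 50.2, 38.3, 65.4, 2495),
    ("region", "Kindia", 2005, 61.5, 50.8, 74.2, 1947),
    ("region", "Kindia", 2012, 40.0, 29.2, 54.5, 2107),
    ("region", "Labe", 2005, 48.4, 35.6, 65.4, 1344),
    ("region", "Labe", 2012, 48.2, 35.3, 65.6, 1296),
    ("region", "Mamou", 2005, 54.8, 45.4, 65.9, 913),
    ("region", "Mamou", 2012, 49.7, 38.0, 64.7, 1008),
    ("region", "Nzerekore", 2005, 62.1, 50.1, 76.7, 3056),
    ("region", "Nzerekore", 2012, 24.2, 17.6, 33.2, 2414),
]

#: National NMR (per 1000 live births) per survey (NMR limited to 1999-2012).
NMR_NATIONAL = {1999: 51.8, 2005: 54.8, 2012: 40.4}

# (indicator, dimension, measure, year, value, ui_low, ui_high)
_SUMMARY_ROWS = [
    ("sba", "wealth_quintile", "D", 1999, 71.7, 66.9, 76.4),
    ("sba", "wealth_quintile", "D", 2005, 71.7, 65.2, 78.2),
    ("sba", "wealth_quintile", "D", 2012, 72.9, 67.2, 78.6),
    ("sba", "wealth_quintile", "D", 2016, 68.5, 63.3, 73.8),
    ("sba", "wealth_quintile", "PAF", 1999, 134.7, 128.6, 140.8),
    ("sba", "wealth_quintile", "PAF", 2005, 123.3, 117.8, 128.9),
    ("sba", "wealth_quintile", "PAF", 2012, 98.4, 93.3, 103.5),
    ("sba", "wealth_quintile", "PAF", 2016, 53.4, 47.9, 58.9),
    ("sba", "wealth_quintile", "PAR", 1999, 48.3, 46.1, 50.4),
    ("sba", "wealth_quintile", "PAR", 2005, 48.0, 45.8, 50.1),
    ("sba", "wealth_quintile", "PAR", 2012, 45.6, 43.2, 47.9),
    ("sba", "wealth_quintile", "PAR", 2016, 33.3, 29.9, 36.7),
    ("sba", "wealth_quintile", "R", 1999, 6.8, 4.9, 8.7),
    ("sba", "wealth_quintile", "R", 2005, 5.7, 3.7, 7.7),
    ("sba", "wealth_quintile", "R", 2012, 4.9, 3.6, 6.1),
    ("sba", "wealth_quintile", "R", 2016, 3.5, 2.9, 4.2),
    ("sba", "education", "D", 1999, 55.3, 49.0, 61.6),
    ("sba", "education", "D", 2005, 52.0, 45.4, 58.6),
    ("sba", "education", "D", 2012, 45.3, 39.14, 51.45),
    ("sba", "education", "D", 2016, 39.1, 34.22, 44.02),
    ("sba", "education", "PAF", 1999, 138.3, 136.1, 140.4),
    ("sba", "education", "PAF", 2005, 119.3, 117.5, 121.1),
    ("sba", "education", "PAF", 2012, 80.2, 78.3, 82.1),
    ("sba", "education", "PAF", 2016, 48.4, 46.5, 50.3),
    ("sba", "education", "PAR", 1999, 49.6, 48.8, 50.3),
    ("sba", "education", "PAR", 2005, 46.4, 45.7, 47.1),
    ("sba", "education", "PAR", 2012, 37.1, 36.2, 38.0),
    ("sba", "education", "PAR", 2016, 30.2, 29.0, 31.3),
    ("sba", "education", "R", 1999, 2.8, 2.5, 3.2),
    ("sba", "education", "R", 2005, 2.6, 2.2, 2.9),
    ("sba", "education", "R", 2012, 2.2, 1.9, 2.4),
    ("sba", "education", "R", 2016, 1.7, 1.6, 1.9),
    ("sba", "residence", "D", 1999, 55.2, 50.0, 60.4),
    ("sba", "residence", "D", 2005, 55.7, 50.3, 61.2),
    ("sba", "residence", "D", 2012, 52.5, 46.9, 58.1),
    ("sba", "residence", "D", 2016, 47.0, 42.3, 51.7),
    ("sba", "residence", "PAF", 1999, 115.0, 112.0, 118.1),
    ("sba", "residence", "PAF", 2005, 110.3, 107.8, 112.8),
    ("sba", "residence", "PAF", 2012, 82.5, 80.3, 84.7),
    ("sba", "residence", "PAF", 2016, 49.5, 47.3, 51.7),
    ("sba", "residence", "PAR", 1999, 41.2, 40.1, 42.3),
    ("sba", "residence", "PAR", 2005, 42.9, 41.9, 43.9),
    ("sba", "residence", "PAR", 2012, 38.2, 37.2, 39.2),
    ("sba", "residence", "PAR", 2016, 30.8, 29.5, 32.2),
    ("sba", "residence", "R", 1999, 3.5, 3.0, 4.1),
    ("sba", "residence", "R", 2005, 3.14, 2.67, 3.61),
    ("sba", "residence", "R", 2012, 2.6, 2.2, 3.0),
    ("sba", "residence", "R", 2016, 2.0, 1.8, 2.2),
    ("sba", "region", "D", 1999, 68.6, 63.4, 73.8),
    ("sba", "region", "D", 2005, 71.3, 64.7, 78.0),
    ("sba", "region", "D", 2012, 70.5, 63.9, 77.2),
    ("sba", "region", "D", 2016, 65.4, 57.0, 73.8),
    ("sba", "region", "PAF", 1999, 142.9, 135.5, 150.4),
    ("sba", "region", "PAF", 2005, 131.7, 122.0, 141.4),
    ("sba", "region", "PAF", 2012, 94.6, 84.6, 104.6),
    ("sba", "region", "PAF", 2016, 53.4, 43.9, 63.0),
    ("sba", "region", "PAR", 1999, 51.2, 48.5, 53.9),
    ("sba", "region", "PAR", 2005, 51.2, 47.4, 55.0),
    ("sba", "region", "PAR", 2012, 43.8, 39.2, 48.4),
    ("sba", "region", "PAR", 2016, 33.3, 27.3, 39.3),
    ("sba", "region", "R", 1999, 4.71, 3.7, 5.7),
    ("sba", "region", "R", 2005, 4.80, 3.5, 6.1),
    ("sba", "region", "R", 2012, 4.6, 3.3, 5.9),
    ("sba", "region", "R", 2016, 3.2, 2.31, 4.0),
    ("nmr", "wealth_quintile", "D", 1999, 17.6, 4.1, 31.1),
    ("nmr", "wealth_quintile", "D", 2005, 21.7, 4.1, 39.3),
    ("nmr", "wealth_quintile", "D", 2012, 17.2, 2.5, 31.8),
    ("nmr", "wealth_quintile", "PAF", 1999, -25.7, -29.6, -21.9),
    ("nmr", "wealth_quintile", "PAF", 2005, -30.2, -33.8, -26.5),
    ("nmr", "wealth_quintile", "PAF", 2012, -21.4, -26.1, -16.7),
    ("nmr", "wealth_quintile", "PAR", 1999, -13.3, -15.3, -11.3),
    ("nmr", "wealth_quintile", "PAR", 2005, -16.5, -18.5, -14.5),
    ("nmr", "wealth_quintile", "PAR", 2012, -8.6, -10.5, -6.7),
    ("nmr", "wealth_quintile", "R", 1999, 1.4, 1.0, 1.8),
    ("nmr", "wealth_quintile", "R", 2005, 1.5, 0.9, 2.1),
    ("nmr", "wealth_quintile", "R", 2012, 1.5, 0.9, 2.1),
    ("nmr", "education", "D", 1999, 29.6, 15.8, 43.4),
    ("nmr", "education", "D", 2005, 13.5, -7.8, 34.9),
    ("nmr", "education", "D", 2012, 17.9, 6.4, 29.5),
    ("nmr", "education", "PAF", 1999, -51.8, -57.9, -45.7),
    ("nmr", "education", "PAF", 2005, -23.0, -30.0, -16.1),
    ("nmr", "education", "PAF", 2012, -41.4, -47.5, -35.4),
    ("nmr", "education", "PAR", 1999, -26.8, -30.0, -23.7),
    ("nmr", "education", "PAR", 2005, -12.6, -16.4, -8.8),
    ("nmr", "education", "PAR", 2012, -16.7, -19.2, -14.3),
    ("nmr", "education", "R", 1999, 2.1, 1.0, 3.3),
    ("nmr", "education", "R", 2005, 1.3, 0.6, 1.9),
    ("nmr", "education", "R", 2012, 1.7, 0.9, 2.5),
    ("nmr", "residence", "D", 1999, 13.7, 4.0, 23.4),
    ("nmr", "residence", "D", 2005, 11.7, 0.5, 23.0),
    ("nmr", "residence", "D", 2012, 6.1, -4.1, 16.4),
    ("nmr", "residence", "PAF", 1999, -19.9, -22.8, -16.9),
    ("nmr", "residence", "PAF", 2005, -16.6, -19.4, -13.7),
    ("nmr", "residence", "PAF", 2012, -11.3, -14.8, -7.9),
    ("nmr", "residence", "PAR", 1999, -10.3, -11.8, -8.8),
    ("nmr", "residence", "PAR", 2005, -9.1, -10.6, -7.5),
    ("nmr", "residence", "PAR", 2012, -4.6, -6.0, -3.2),
    ("nmr", "residence", "R", 1999, 1.3, 1.0, 1.6),
    ("nmr", "residence", "R", 2005, 1.2, 0.9, 1.5),
    ("nmr", "residence", "R", 2012, 1.1, 0.8, 1.4),
    ("nmr", "child_sex", "D", 1999, 15.2, 5.9, 24.4),
    ("nmr", "child_sex", "D", 2005, 17.3, 7.5, 27.0),
    ("nmr", "child_sex", "D", 2012, 12.1, 3.2, 20.9),
    ("nmr", "child_sex", "PAF", 1999, -15.1, -16.8, -13.3),
    ("nmr", "child_sex", "PAF", 2005, -16.2, -17.8, -14.6),
    ("nmr", "child_sex", "PAF", 2012, -15.3, -17.3, -13.2),
    ("nmr", "child_sex", "PAR", 1999, -7.8, -8.7, -6.9),
    ("nmr", "child_sex", "PAR", 2005, -8.9, -9.7, -8.0),
    ("nmr", "child_sex", "PAR", 2012, -6.1, -7.0, -5.3),
    ("nmr", "child_sex", "R", 1999, 1.3, 1.1, 1.5),
    ("nmr", "child_sex", "R", 2005, 1.3, 1.1, 1.6),
    ("nmr", "child_sex", "R", 2012, 1.3, 1.0, 1.6),
    ("nmr", "region", "D", 1999, 18.6, 3.3, 33.8),
    ("nmr", "region", "D", 2005, 35.4, 11.8, 58.9),
    ("nmr", "region", "D", 2012, 25.9, 10.4, 41.3),
    ("nmr", "region", "PAF", 1999, -16.7, -21.2, -12.2),
    ("nmr", "region", "PAF", 2005, -32.4, -36.9, -27.9),
    ("nmr", "region", "PAF", 2012, -39.9, -43.8, -35.9),
    ("nmr", "region", "PAR", 1999, -8.6, -11.0, -6.3),
    ("nmr", "region", "PAR", 2005, -17.8, -20.2, -15.3),
    ("nmr", "region", "PAR", 2012, -16.1, -17.7, -14.5),
    ("nmr", "region", "R", 1999, 1.4, 1.0, 1.8),
    ("nmr", "region", "R", 2005, 1.9, 0.9, 2.9),
    ("nmr", "region", "R", 2012, 2.0, 1.2, 2.9),
]

_EST_COLS = ["dimension", "subgroup", "survey_year", "estimate", "ui_low", "ui_high", "pop_n"]


def sba_estimates(survey_year: int | None = None) -> pd.DataFrame:
    """Published disaggregated SBA coverage (%), optionally for one survey."""
    df = pd.DataFrame(_SBA_ROWS, columns=_EST_COLS)
    if survey_year is not None:
        df = df[df["survey_year"] == survey_year].reset_index(drop=True)
    return df


def nmr_estimates(survey_year: int | None = None) -> pd.DataFrame:
    """Published disaggregated NMR (per 1000 live births)."""
    df = pd.DataFrame(_NMR_ROWS, columns=_EST_COLS)
    if survey_year is not None:
        df = df[df["survey_year"] == survey_year].reset_index(drop=True)
    return df


def published_summary_measures() -> pd.DataFrame:
    """Published D/R/PAR/PAF values with their 95% uncertainty intervals."""
    return pd.DataFrame(
        _SUMMARY_ROWS,
        columns=["indicator", "dimension", "measure", "survey_year",
                 "value", "ui_low", "ui_high"],
    )


def published_disaggregation(indicator: str, dimension: str,
                             survey_year: int) -> pd.DataFrame:
    """Published subgroup estimates in disaggregation-table shape.

    One row per subgroup plus a ``national`` row, with columns matching the
    output of :func:`equimeasure.estimation.disaggregate`, so the published
    numbers can be fed straight into the summary-measure operations.
    """
    source = sba_estimates if indicator == "sba" else nmr_estimates
    sub = source(survey_year)
    sub = sub[sub["dimension"] == dimension]
    if sub.empty:
        raise KeyError(f"no published {indicator} estimates for "
                       f"{dimension!r} in {survey_year}")
    rows = sub[["dimension", "subgroup", "estimate", "ui_low", "ui_high",
                "pop_n"]].copy()
    rows["se"] = 0.0
    nat = national_average(indicator, survey_year)
    rows = pd.concat([rows, pd.DataFrame([{
        "dimension": dimension, "subgroup": "national", "estimate": nat,
        "ui_low": nat, "ui_high": nat, "pop_n": int(sub["pop_n"].sum()),
        "se": 0.0}])], ignore_index=True)
    return rows[["dimension", "subgroup", "estimate", "se", "ui_low",
                 "ui_high", "pop_n"]]


def national_average(indicator: str, survey_year: int) -> float:
    """Published national average for an indicator and survey year."""
    table = SBA_NATIONAL if indicator == "sba" else NMR_NATIONAL
    try:
        return table[survey_year]
    except KeyError:
        raise KeyError(f"no published national {indicator} value for "
                       f"{survey_year}") from None
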