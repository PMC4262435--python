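"""Published reference values for ten trans-oceanic juvenile osprey tracks.

Ten <1-year-old ospreys (Pandion haliaetus) tagged in New England
(2007-2012) made non-stop southward migrations over the western Atlantic
Ocean.  Piecewise-linear breakpoint segmentation of the hourly GPS
tracks yielded 25 constant-course segments; the per-segment summary
statistics (endpoints, distance, duration, speed, direction,
straightness) and the corresponding straightness of the same segments in
nest-origin transformed magnetic coordinates were published as summary
tables.  The raw hourly fixes were never deposited, so these summary
rows serve as report-level fixtures: they let the reporting and
cross-space comparison code be exercised against real numbers without
access to the original tracks.

``segment_summaries()`` and ``natal_straightness()`` return the rows as
DataFrames; ``nest_sites()`` returns each bird's tagging location and
date (the natal-frame anchor).
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["segment_summaries", "natal_straightness", "nest_sites"]

# 25 constant-course trans-oceanic migration segments.  speed/direction
# columns carry the mean with ±1σ in the paired *_sd columns.
_SEGMENTS_TSV = """\
bird	segment	start_lat	start_lon	end_lat	end_lon	n_fixes	distance_km	duration_h	speed_kmh	speed_sd	direction_deg	direction_sd	straightness
Bea	1	41.3525	-70.4550	36.8677	-70.6928	13	507.3	12.0	42.2	8.7	184.9	9.9	0.9839
Bea	2	32.4588	-72.6775	24.6273	-75.6693	14	925.2	19.3	47.8	8.7	200.8	9.2	0.9927
Belle	1	41.4342	-70.6035	34.9578	-67.6265	12	674.2	11.0	61.2	4.3	160.3	6.0	0.9950
Belle	2	30.1502	-66.4967	25.0915	-66.9767	13	566.1	12.1	46.9	4.1	184.9	4.4	0.9972
Belle	3	21.7278	-70.6900	21.1202	-71.4668	4	105.2	3.0	35.0	5.1	229.8	3.8	0.9986
Caley	1	41.3758	-70.5095	38.7020	-69.5030	4	180.3	3.0	60.0	4.4	165.9	3.0	0.9992
Caley	2	38.2512	-69.5047	35.0937	-70.2163	9	361.9	8.2	44.0	3.1	189.9	10.1	0.9858
Caley	3	30.3983	-73.8658	26.9340	-73.4510	10	388.0	9.0	43.1	4.4	174.0	3.7	0.9982
Caley	4	26.3837	-73.5220	24.6775	-75.6710	3	287.3	8.2	35.1	1.2	227.1	3.1	0.9996
Felix	1	41.3398	-70.6032	28.5815	-78.0095	21	1572.1	31.0	50.6	6.3	203.7	7.3	0.9983
Felix	2	28.2437	-78.0543	27.1933	-78.2622	3	122.3	2.3	53.3	14.5	188.7	20.3	0.9692
Henrietta	1	41.4625	-70.6238	34.5040	-72.4998	14	1008.0	18.7	54.0	17.6	192.3	7.1	0.9941
Henrietta	2	31.4662	-74.7465	26.5962	-77.0080	14	674.5	18.4	36.7	5.1	202.1	9.8	0.9882
Isabel	1	41.3443	-70.7728	30.7875	-70.1300	15	1179.7	24.9	47.3	17.6	178.4	6.3	0.9963
Isabel	2	30.3745	-70.1795	25.6753	-73.2575	8	611.9	15.5	39.5	10.6	206.3	13.6	0.9863
Isabel	3	25.3978	-73.2572	22.6772	-73.9887	11	339.0	11.1	30.6	5.2	198.4	24.5	0.9190
Luke	1	41.2717	-70.66933	30.0965	-70.1470	13	1246.5	24.0	51.9	10.6	181.4	3.8	0.9979
Luke	2	26.1322	-71.8860	21.4823	-72.9247	14	383.6	13.1	29.2	3.5	186.8	8.5	0.9926
Mittark	1	41.36383	-70.65233	37.4155	-72.0177	10	588.4	10.7	55.0	9.3	194.5	4.4	0.9971
Mittark	2	31.9525	-76.22067	30.8112	-76.4960	4	151.4	3.5	43.2	1.7	194.8	6.7	0.9988
Mittark	3	30.39383	-76.70983	27.1190	-80.19483	9	635.7	13.1	48.6	1.8	219.4	9.5	0.9800
Moffet	1	41.4305	-70.5928	37.2007	-68.9812	11	491.8	10.0	49.1	3.3	164.4	5.0	0.9970
Moffet	2	33.1452	-68.2823	20.4677	-74.5888	27	1558.0	43.9	35.4	6.6	202.6	8.6	0.9894
Chip	1	41.4978	-71.4515	39.8313	-71.4847	6	186.2	5.0	37.2	2.6	179.4	6.8	0.9952
Chip	2	39.5482	-71.4317	37.2432	-73.1692	8	302.8	7.0	43.2	6.5	211.0	12.0	0.9831
"""

# Straightness of the same 25 segments traced in the nest-origin
# transformed magnetic (y_T-z_T) plane, with the published per-axis
# standard errors of the linear trace fit (nT).
_NATAL_TSV = """\
bird	segment	straightness	zT_se_nT	yT_se_nT
Bea	1	0.9516	350.0	63.5
Bea	2	0.9965	107.6	37.3
Belle	1	0.9959	424.7	18.3
Belle	2	0.9872	454.6	49.5
Belle	3	0.9834	39.3	74.6
Caley	1	0.9994	104.5	14.1
Caley	2	0.9826	336.2	137.1
Caley	3	0.9962	144.2	18.7
Caley	4	0.9999	4.3	5.1
Felix	1	0.9616	244.4	110.1
Felix	2	1.0000	4.5	1.2
Henrietta	1	0.9790	229.5	56.8
Henrietta	2	0.9913	55.7	19.6
Isabel	1	0.9947	205.5	31.4
Isabel	2	0.9861	120.7	57.9
Isabel	3	0.7772	186.0	75.6
Luke	1	0.9951	220.7	45.1
Luke	2	0.9699	176.6	29.9
Mittark	1	0.9402	115.7	30.5
Mittark	2	0.9998	7.9	4.0
Mittark	3	0.9938	34.2	28.2
Moffet	1	0.9898	719.0	48.1
Moffet	2	0.9659	287.3	111.4
Chip	1	0.9052	234.3	73.6
Chip	2	0.9864	47.7	20.8
"""

# Tagging (nest-area capture) locations and dates per bird.
_NESTS_TSV = """\
bird	tag_date	lat	lon
Bea	2009-08-05	41.3873	-70.4707
Belle	2010-07-28	41.4692	-70.6235
Caley	2009-08-03	41.3732	-70.5027
Felix	2007-08-16	41.5783	-70.6168
Henrietta	2011-05-24	41.4667	-70.5673
Isabel	2009-08-01	41.4672	-70.5662
Luke	2007-07-27	41.4750	-70.6125
Mittark	2008-09-16	41.4025	-70.68233
Moffet	2009-08-04	41.4157	-70.5637
Chip	2012-08-02	43.4577	-71.5682
"""


def segment_summaries() -> pd.DataFrame:
    """The 25 published constant-course segment summary rows."""
    return pd.read_csv(io.StringIO(_SEGMENTS_TSV), sep="\t")


def natal_straightness() -> pd.DataFrame:
    """Published y_T-z_T straightness and per-axis SEs for the 25 segments."""
    return pd.read_csv(io.StringIO(_NATAL_TSV), sep="\t")


def nest_sites() -> pd.DataFrame:
    """Tagging location and date for each of the ten birds."""
    df = pd.read_csv(io.StringIO(_NESTS_TSV), sep="\t")
    df["tag_date"] = pd.to_datetime(df["tag_date"])
    return df
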