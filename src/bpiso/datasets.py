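"""Bundled example data: a published multi-condition culture study of
*Sulfolobus acidocaldarius*.

The study grew the thermoacidophile under five environmental-condition
experiments — growth temperature (65–80°C), pH (2–4), shaking/aeration
rate (50–300 RPM), O2 mixing ratio (0.2–20%), and electron-donor
(sucrose) flux in chemostats (doubling times 7–44 h) — and reported, per
treatment: growth statistics and media-water δ²H; relative abundances of
the four iGDGT-derived biphytanes (BP-0..BP-3) with the biphytane Ring
Index; and calibrated δ²H_BP, lipid/water fractionation ²ε_L/W, and ring
differences Δε/ring, each with 1σ. Values are as printed (δ/ε to integer
‰, abundances and RI to 2 decimals); BP-3 entries that were below the
measurement limit are missing ("n.d.").

These tables are treatment-level reductions, suitable as worked-example
inputs for the fractionation and study-statistics layers (the raw
peak-level data behind them are not bundled; use the synthetic generator
for peak-level work).
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["culture_conditions", "bp_abundances", "bp_isotopes", "EXPERIMENTS"]

EXPERIMENTS = ("temperature", "pH", "aeration", "O2", "edonor")

# experiment, treatment, N, temp C, pH, RPM, O2, water d2H, mu mean/sd,
# doubling time mean/sd (h), max OD600 mean/sd
_CONDITIONS = """\
experiment	treatment	n	temp_c	ph	rpm	o2	d2h_water_permil	mu_mean	mu_sd	td_mean	td_sd	max_od_mean	max_od_sd
temperature	65	5	65	3	200	air	-47.6	0.09	0.02	8.03	1.53	1.37	0.12
temperature	70	5	70	3	200	air	-55.0	0.10	0.01	7.07	0.65	1.96	0.14
temperature	75	5	75	3	200	air	-54.2	0.16	0.02	4.38	0.60	1.61	0.23
temperature	80	5	80	3	200	air	-52.7	0.19	0.01	3.73	0.19	1.65	0.21
pH	2	5	70	2	200	air	-59.8	0.12	0.01	5.75	0.43	0.71	0.04
pH	3	5	70	3	200	air	-55.0	0.10	0.01	7.07	0.65	1.96	0.14
pH	4	5	70	4	200	air	-60.9	0.10	0.01	6.63	0.41	0.49	0.03
aeration	50	5	70	3	50	air	-47.6	0.02	0.00	32.75	1.50	0.22	0.01
aeration	125	5	70	3	125	air	-46.3	0.08	0.00	8.82	0.51	0.73	0.01
aeration	300	5	70	3	300	air	-46.9	0.07	0.00	9.26	0.25	0.63	0.02
O2	0.2	3	70	3	200	0.2	-46.9	0.02	0.00	33.05	8.64	0.08	0.00
O2	0.5	3	70	3	200	0.5	-55.6	0.05	0.02	14.17	4.54	0.10	0.00
O2	2	3	70	3	200	2.0	-51.3	0.09	0.01	7.42	0.63	0.24	0.02
O2	20	3	70	3	200	20	-51.0	0.34	0.21	2.58	1.36	0.32	0.04
edonor	7	6	70	2.25	200	20	-59.7	0.14	0.00	7.00	0.09	0.84	0.10
edonor	21	9	70	2.25	200	20	-59.5	0.05	0.00	21.00	0.45	0.88	0.03
edonor	44	6	70	2.25	200	20	-50.1	0.02	0.00	44.30	5.68	1.12	0.04
"""

# per-treatment relative abundances of BP-0..BP-3 (±sd) and Ring Index
_ABUNDANCES = """\
experiment	treatment	n	bp0	bp0_sd	bp1	bp1_sd	bp2	bp2_sd	bp3	bp3_sd	ri_mean	ri_sd
temperature	65	1	0.06	0.00	0.15	0.01	0.76	0.00	0.03	0.00	1.77	0.01
temperature	70	1	0.12	0.04	0.26	0.03	0.61	0.07	0.01	0.00	1.52	0.15
temperature	75	1	0.06	0.01	0.13	0.01	0.60	0.02	0.21	0.02	1.97	0.07
temperature	80	1	0.07	0.01	0.14	0.00	0.46	0.01	0.33	0.01	2.04	0.02
pH	2	1	0.18	0.00	0.31	0.00	0.36	0.00	0.15	0.00	1.48	0.00
pH	3	1	0.12	0.04	0.26	0.03	0.61	0.07	0.01	0.00	1.52	0.15
pH	4	1	0.05	0.00	0.15	0.01	0.72	0.01	0.07	0.00	1.81	0.02
aeration	50	1	0.22	0.01	0.35	0.02	0.41	0.01	0.02	0.00	1.23	0.02
aeration	125	1	0.07	0.00	0.18	0.01	0.70	0.01	0.05	0.00	1.74	0.03
aeration	300	1	0.07	0.00	0.19	0.01	0.68	0.01	0.06	0.00	1.72	0.01
O2	0.2	2	0.09	0.02	0.26	0.05	0.55	0.06	0.09	0.01	1.64	0.25
O2	0.5	1	0.11	0.02	0.35	0.07	0.51	0.09	0.02	0.01	1.43	0.38
O2	2	3	0.25	0.01	0.44	0.00	0.31	0.02	0.01	0.00	1.08	0.41
O2	20	3	0.18	0.02	0.38	0.05	0.36	0.05	0.08	0.12	1.35	0.80
edonor	7	1	0.31	0.00	0.39	0.01	0.28	0.00	0.02	0.00	1.01	0.01
edonor	21	1	0.22	0.00	0.35	0.00	0.39	0.00	0.03	0.00	1.23	0.02
edonor	44	1	0.13	0.00	0.27	0.00	0.54	0.01	0.06	0.00	1.53	0.02
"""

# per-treatment δ²H_BP and ²ε_L/W (±sd) per moiety, per-moiety Δε/ring
# (±sd, BP-1..BP-3), and abundance-weighted means; blank = n.d.
_ISOTOPES = """\
experiment	treatment	bp0_d2h	bp0_d2h_sd	bp0_eps	bp0_eps_sd	bp1_d2h	bp1_d2h_sd	bp1_eps	bp1_eps_sd	bp1_dering	bp1_dering_sd	bp2_d2h	bp2_d2h_sd	bp2_eps	bp2_eps_sd	bp2_dering	bp2_dering_sd	bp3_d2h	bp3_d2h_sd	bp3_eps	bp3_eps_sd	bp3_dering	bp3_dering_sd	wm_d2h	wm_d2h_sd	wm_eps	wm_eps_sd	wm_dering	wm_dering_sd
temperature	65	-234	18	-195	19	-232	5	-193	5	2	19	-243	3	-205	3	-9	6							-241	6	-203	5	-5	0
temperature	70	-221	8	-175	9	-225	5	-180	5	-5	10	-225	3	-180	3	-2	4							-225	5	-180	4	-3	0
temperature	75	-262	4	-220	5	-256	4	-214	5	6	7	-268	5	-226	6	-8	4	-268	4	-227	4	-3	3	-266	5	-224	5	-3	2
temperature	80	-253	13	-211	13	-248	6	-206	7	5	15	-262	5	-221	5	-10	6	-260	3	-219	3	-2	3	-259	5	-218	6	-4	3
pH	2	-258	25	-211	27	-252	19	-205	20	6	34	-248	11	-200	11	5	14	-228	22	-179	24	15	11	-248	22	-200	19	10	9
pH	3	-221	8	-175	9	-225	5	-180	5	-5	10	-225	3	-180	3	-2	4							-225	4	-180	4	-3	0
pH	4	-249	9	-201	10	-251	6	-202	6	-1	12	-261	5	-214	6	-9	5	-257	6	-209	7	-1	4	-259	5	-211	6	-4	3
aeration	50	-230	3	-192	3	-227	5	-189	5	3	6	-232	4	-193	4	-3	4	-222	34	-183	36	5	14	-230	6	-191	7	2	10
aeration	125	-235	12	-198	12	-231	7	-194	7	4	15	-239	7	-202	7	-5	6	-239	21	-202	22	-2	9	-237	9	-200	9	-2	7
aeration	300	-238	6	-201	7	-240	5	-202	5	-2	8	-244	2	-207	2	-4	3	-254	13	-217	13	-8	5	-243	4	-206	4	-5	4
O2	0.2	-244	2	-208	8	-275	7	-239	3	-31	5	-231	13	-193	17	20	3	-231	9	-194	15	12	1	-248	9	-213	7	7	3
O2	0.5	-255	5	-211	5	-237	4	-192	5	11	8	-239	5	-194	6	5	4							-244	4	-200	5	7	0
O2	2	-243	5	-202	6	-242	2	-201	4	1	0	-242	4	-200	5	1	0							-242	5	-201	5	1	1
O2	20	-243	1	-202	1	-243	4	-202	5	0	2	-246	5	-205	5	-2	1							-244	5	-203	6	-2	2
edonor	7	-280	7	-234	7	-276	4	-230	4	4	8	-272	6	-226	5	4	4	-253	17	-205	19	14	8	-276	6	-230	6	9	6
edonor	21	-261	6	-214	6	-261	5	-214	6	0	8	-257	5	-210	5	3	4	-237	18	-189	20	14	8	-259	5	-212	6	8	6
edonor	44	-253	4	-214	5	-246	6	-207	6	7	7	-242	3	-202	3	5	4	-239	5	-199	5	4	2	-244	4	-205	4	5	2
"""


def _parse(text: str) -> pd.DataFrame:
    df = pd.read_csv(StringIO(text), sep="\t", dtype={"treatment": str})
    return df


def culture_conditions() -> pd.DataFrame:
    """Treatment-level culture conditions and growth statistics.

    Columns include the manipulated condition levels, the media-water
    δ²H at lipid sampling (‰ VSMOW), and mean ± sd of the specific
    growth rate μ (h⁻¹), doubling time T_D (h), and maximum OD600.
    The electron-donor flux rows are chemostats: their T_D is the set
    dilution time and their printed μ is not ln(2)/T_D.
    """
    return _parse(_CONDITIONS)


def bp_abundances() -> pd.DataFrame:
    """Treatment-level relative abundances of BP-0..BP-3 and Ring Index."""
    return _parse(_ABUNDANCES)


def bp_isotopes() -> pd.DataFrame:
    """Treatment-level δ²H_BP, ²ε_L/W, Δε/ring per moiety plus
    abundance-weighted means (all in ‰; missing = below detection)."""
    df = _parse(_ISOTOPES)
    return df
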