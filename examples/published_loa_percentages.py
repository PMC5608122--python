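"""Normalized LOA percentages from the packaged published summary tables.

Joins the published Bland-Altman LOA ranges with the distribution medians
and recomputes LOA%/median x 100 for every metric.
"""

from vesselrep import normalized_loa_table

table = normalized_loa_table()
t2w = table[table["weighting"] == "T2W"].copy()
t2w["loa_pct"] = t2w["loa_pct"].round(1)
print(t2w[["metric", "sequence", "bias", "loa_range", "median", "loa_pct"]].to_string(index=False))
print()
print("T2W intensity metrics: the ungated arm's normalized LOA percentages")
print("(muscle SNR 7.6%, wall SNR 22.4%, wall CNR 34.9%) are well below the")
print("gated arm's (52.3% / 30.0% / 42.5%) - the repeatability advantage of")
print("fixed-TR acquisition, normalized for the arms' different SNR levels.")
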