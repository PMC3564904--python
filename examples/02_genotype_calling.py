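"""Call a diploid genotype from triplicate fragment-analysis peaks.

Synthesises three replicate electropherograms for a heterozygous 106/103
locus with 15% PCR stutter, then applies the intensity-threshold caller:
homozygote when the 2nd and 3rd peaks are within 10^4 U of each other,
heterozygote when the 2nd peak clears 80% of the top peak, ambiguous
otherwise or when replicates disagree.
"""

import fatemap as fm

trip = fm.simulate_peak_profiles((106, 103), fm.StutterModel(ratio=0.15), seed=4)
call = fm.call_locus_genotype(trip, fm.CallThresholds())
print(f"clean triplicate        -> {call} ({call.status})")

# one replicate drops the second allele: the call is no longer reproducible
bad = fm.simulate_peak_profiles((106, 103), seed=4, dropout_replicates=(2,))
call = fm.call_locus_genotype(bad)
print(f"with replicate dropout  -> {call} ({call.status})")
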