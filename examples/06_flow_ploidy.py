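"""Call ploidy from simulated flow-cytometry histograms.

The G0/G1 peak position of PI-stained nuclei scales with DNA content, so
the ratio of a sample's peak to that of a diploid external standard gives
its ploidy multiple; the peak CV is the staining-quality metric.
"""

from repeatscreen.flow import ploidy_from_histograms
from repeatscreen.simulate import simulate_histogram

standard = simulate_histogram(
    standard_peak_position=100, sample_ploidy_multiple=2, cv=0.03,
    n_events=20_000, seed=7,
)
for multiple in (2, 4, 6, 9):
    sample = simulate_histogram(100, multiple, 0.03, 20_000, seed=multiple)
    call, speak, tpeak = ploidy_from_histograms(sample, standard)
    print(f"planted {multiple}x -> FL={speak.position:6.1f}  CV={speak.cv:.3f}  "
          f"ratio={call.ratio:5.2f}  called {call.multiple}x  "
          f"ambiguous={call.ambiguous}")

print("\nFL grows linearly with ploidy; CVs near 0.03 are in the routine 2-5 %")
print("quality band, and an integer ratio means an unambiguous call.")
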