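"""Verifying a probabilistic forecast and its expected long-run miss rate.

Checks the 2016 increment forecast against the observed value, and shows
why even a perfectly calibrated +/- 2 s.d. forecast must eventually miss:
the per-year miss chance is the Gaussian tail mass (~4.55%), which
compounds over the years.
"""

from ninocast import VerificationReport, gaussian_coverage, miss_probability

report = VerificationReport()
report.add("annual increment (ppm)", central=3.15, two_sd=0.53, observed=3.39)
report.add("annual mean 2016 (ppm)", central=404.45, two_sd=0.53, observed=404.28)
report.add("September 2016 (ppm)", central=401.20, two_sd=0.53, observed=401.01)
print(report.to_text())

miss = 1.0 - gaussian_coverage()
print(f"\nper-year miss probability of a calibrated 2 s.d. forecast: {100 * miss:.2f}%")
for k in (5, 10, 15):
    print(f"  P(at least one miss in {k:2d} years) = {100 * miss_probability(k):.0f}%")
print("A good forecast system therefore shows a predictable rate of misses;")
print("an occasional miss is evidence of honest uncertainty, not failure.")
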