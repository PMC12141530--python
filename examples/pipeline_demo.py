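"""The full demo report: every synthetic scene vs its closed form.

Runs each generator, pushes its scene through the matching stage, and
prints the expected-versus-measured table — the package's self-check.
"""

import epiquant as eq

report = eq.demo_report(seed=1)
print(report.to_string(index=False))
print()
print("Each row pairs a closed-form expectation (derivation in the last")
print("column) with the value the pipeline actually measured on a scene")
print("generated with that ground truth.")
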