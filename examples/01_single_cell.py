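"""Pace one epicardial myocyte and report its action potential.

Applies the protocol's stimulus pulse (72 uA/uF for 1 ms) to a resting cell
and prints the resting potential, the AP peak, and APD90 -- the duration at
90% repolarization, the standard summary of ventricular AP shape (~300 ms
for the epicardial variant of the 2006 human ventricular model).
"""

from hearts import cell

t, vm = cell.run_cell("epi", duration_ms=450.0, dt=0.02,
                      pulses=[(10.0, 1.0, 72.0)])
print(f"resting Vm : {cell.initial_state('epi').Vm:7.1f} mV")
print(f"AP peak    : {vm.max():7.1f} mV")
print(f"APD90      : {cell.apd90(t, vm):7.1f} ms")
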