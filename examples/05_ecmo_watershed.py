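"""Cardiogenic shock with VA-ECMO support: flows, pressures, watershed.

Cardiac output is reduced by 70% (5 -> 1.5 L/min) and a constant retrograde
ECMO flow is injected at the descending aorta (0, 4 or 6 L/min). The
watershed is the most proximal axial position where the net aortic flow
changes sign: retrograde ECMO blood supplies everything distal of it, the
ventricle everything proximal.
"""

import aortaflow as af
from aortaflow import hemodynamics as hd

geometry = af.build_geometry(af.AortaParams(), label="template")
tracts = af.split_tracts(geometry.centerline_tree)

healthy = hd.default_cardiac_waveform(mean_lmin=5.0)
net_h = hd.build_network(tracts)
wk = hd.calibrate_rcr(net_h, healthy)

shock = hd.scale_waveform(healthy, reduction=0.70)
net = hd.build_network(tracts, with_ecmo_return=True)
net.windkessels = dict(wk)

print(f"shock cardiac output: {shock.cycle_mean_lmin:.2f} L/min")
print(f"{'EF':>4} {'peak P':>8} {'supra Qmean':>12} {'watershed sys':>16} {'watershed dia':>16}")
for ef in (0.0, 4.0, 6.0):
    cfg = hd.SimulationConfig(ef_lmin=ef, mode="shock")
    res = hd.simulate(net, shock, cfg)
    hd.transport_fraction(res, net)
    means = res.mean_outlet_flows_lmin()
    supra = means["BCA"] + means["LCCA"] + means["LSA"]
    ws_s = hd.watershed_location(res, net, "systolic")
    ws_d = hd.watershed_location(res, net, "diastolic")
    print(f"{ef:4.0f} {res.peak_root_pressure_mmhg():7.1f}  {supra:8.2f} L/min"
          f" {ws_s.zone:>16} {ws_d.zone:>16}")

print("\nHigher support raises root pressure (afterload) and restores supra-aortic")
print("perfusion linearly in EF. At the systolic peak the instantaneous cardiac jet")
print("keeps the whole aorta antegrade in this resistive model (zone 'none'); in")
print("diastole the inflow pauses and retrograde ECMO flow reaches the ascending")
print("aorta. Cycle-averaged, the watershed sits between those extremes and moves")
print("proximally with EF (see the steady-flow example in the test suite).")
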