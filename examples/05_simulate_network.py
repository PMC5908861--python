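"""Simulate the clustered GIF network and analyze it like a recording.

Builds the baseline topology (3000 excitatory + 900 inhibitory neurons,
one embedded 95-neuron cluster), simulates 30 s, reads the spikes out
on 60 virtual MEA channels and runs burst detection and the spectrum —
the full recording-analysis chain on mechanistic synthetic data.

Runtime: roughly a minute on one CPU.
"""

from neuroburst import detect_bursts, dominant_frequency, gif, msdf, power_spectrum

top = gif.build_topology("fig6_baseline")
res = gif.simulate(top, duration=30.0, dt=0.2, seed=1)
sts = gif.readout(res, gif.make_channel_map(res.n_neurons, seed=1))

print(f"network spikes: {res.spike_times.size} "
      f"(population rate {res.population_rate():.2f} Hz/neuron)")
catalog = detect_bursts(sts)
print(f"synchronized bursts: {catalog.n_bursts} ({catalog.burst_rate:.2f} Hz)")
print(f"mean BD {catalog.summary()['mean_bd_s']:.2f} s, "
      f"mean IBI {catalog.summary()['mean_ibi_s']:.2f} s")
print(f"dominant mSDF frequency: {dominant_frequency(power_spectrum(msdf(sts))):.2f} Hz")
print("# the cluster ignites dish-wide bursts at 0.1-0.5 Hz and slow\n"
      "# adaptation silences them - the in vitro slow-oscillation regime.")
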