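condition,spiked_ug_ml,measured_ug_ml,accuracy_pct
bench-top,0.1,0.096,96.0
bench-top,0.8,0.783,97.87
bench-top,1.6,1.571,98.18
bench-top,2.0,1.944,97.20
freeze-thaw,0.1,0.099,99.00
freeze-thaw,0.8,0.795,99.37
freeze-thaw,1.6,1.582,98.87
freeze-thaw,2.0,1.995,99.75
one-week,0.1,0.093,93.00
one-week,0.8,0.746,93.25
one-week,1.6,1.517,94.81
one-week,2.0,1.911,95.55
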