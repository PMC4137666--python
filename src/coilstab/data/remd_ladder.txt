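# Reference 64-rung REMD temperature ladder (K), 303.15-809.57 K,
# produced by an exponential temperature generator tuned for ~0.5
# exchange probability. One temperature per line.
303.15
307.90
312.72
317.61
322.59
327.64
332.77
337.99
343.29
348.68
354.15
359.70
365.35
371.08
376.92
382.83
388.86
394.97
401.18
407.48
413.91
420.41
427.03
433.73
440.55
447.48
454.52
461.68
468.95
476.33
483.83
491.44
499.18
507.03
515.01
523.11
531.35
539.71
547.96
556.59
565.34
574.24
583.28
592.47
601.81
611.28
620.84
630.62
640.54
650.63
660.87
671.28
681.85
692.57
703.47
714.55
725.79
737.21
748.80
760.60
772.55
784.71
797.04
809.57
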