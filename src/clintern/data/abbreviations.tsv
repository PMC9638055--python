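b.i.d.	Frequency	twice a day	RPT12H
t.i.d.	Frequency	three times a day	RPT8H
q.i.d.	Frequency	four times a day	RPT6H
q.d.	Frequency	once a day	RP1D
q.o.d.	Frequency	every other day	RP2D
q.h.s.	Frequency	nightly	RP1D
q.a.m.	Frequency	every morning	RP1D
p.r.n.	Frequency	as needed
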