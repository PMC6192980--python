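model	term	value
model1	miR-320a	0.581
model1	miR-665	0.691
model1	miR-3184-5p	-0.704
model1	miR-6717-5p	-0.313
model1	miR-4459	-1.302
model1	miR-6076	0.729
model1	miR-3195	0.676
model1	miR-1275	0.716
model1	miR-3185	0.672
model1	miR-4640-5p	-0.384
model1	(intercept)	-9.375
model2	miR-4687-3p	0.996
model2	miR-939-5p	-0.741
model2	miR-5739	0.718
model2	miR-211-3p	-0.798
model2	miR-1273g-3p	0.719
model2	miR-3663-3p	1.036
model2	miR-4726-5p	0.520
model2	miR-4745-5p	-0.583
model2	miR-1268b	0.786
model2	miR-658	-0.223
model2	(intercept)	-25.0
model3	miR-663b	0.715
model3	miR-4730	-0.710
model3	miR-642a-3p	0.254
model3	miR-658	0.628
model3	miR-486-3p	0.013
model3	miR-1246	-0.0519
model3	miR-1207-5p	0.317
model3	miR-4419b	0.179
model3	miR-6124	-0.264
model3	(intercept)	-7.2
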