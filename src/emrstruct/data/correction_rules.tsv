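# Default correction-rule table. Order is application order.
# original<TAB>replacement ; empty/missing replacement deletes.
# -- full-width digits -> ASCII (keeps the lab-value regexes single-form)
０	0
１	1
２	2
３	3
４	4
５	5
６	6
７	7
８	8
９	9
# -- full-width latin seen in pasted lab panels
Ｗ	W
Ｂ	B
Ｃ	C
Ｈ	H
ｂ	b
Ｌ	L
Ｐ	P
Ｔ	T
# -- common EMR typos / variant characters
圧	压
抦	病
曰	日
# -- fold full-width space to ASCII space
　	 

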