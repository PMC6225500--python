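position	75	79	116	117	118	136	152	209	242	247	427	445	447	465	478	479	483	492	493	546	550	558	565	580	586	599	602	611	620	622	641
U. rhynchophylloides	T	G	A	C	T	T	A	T	G	G	G	G	C	T	C	C	A	C	G	C	-	G	T	T	C	G	-	T	T	T	C
U. rhynchophylla	.	.	.	T	C	.	G	.	.	K	.	.	.	.	.	.	.	Y	.	.	-	.	.	C	.	.	-	.	.	.	.
U. sinensis	.	.	.	.	C	.	G	.	.	A	.	.	T	.	.	.	.	.	T	.	-	.	.	C	.	.	-	.	.	.	.
U. homomalla	.	.	.	.	C	.	G	.	.	.	.	.	.	.	T	.	.	.	.	.	-	.	.	C	.	T	-	.	.	.	.
U. hirsuta	.	T	.	.	C	.	G	.	A	.	.	.	.	C	.	.	.	.	.	.	-	.	.	C	.	.	-	.	.	.	.
U. sessilifructus	.	.	C	.	C	.	G	.	.	.	T	.	.	.	.	.	M	.	.	.	C	W	.	C	A	.	-	.	.	.	A
U. macrophylla	C	.	.	.	C	.	G	C	.	.	.	S	.	.	.	.	.	.	.	.	-	.	C	C	.	.	-	.	.	.	.
U. laevigata	.	.	R	.	C	.	G	.	.	.	.	.	.	.	.	.	G	.	.	A	-	.	.	C	.	.	-	.	.	.	.
U. lancifolia	.	.	.	.	Y	.	G	.	.	.	.	.	.	.	.	.	.	.	.	.	-	.	.	C	.	.	-	.	.	.	.
U. lanosa	.	.	.	.	C	C	G	.	.	.	.	.	.	.	.	.	.	.	.	.	-	.	.	C	.	.	-	T	C	A	.
U. scandens	.	.	.	.	C	.	G	.	.	.	.	.	.	.	.	T	.	.	.	.	-	.	.	C	.	K	-	.	.	.	.
U. yunnanensis	.	.	.	.	C	C	G	.	.	.	.	.	.	.	.	.	.	.	.	.	-	.	.	C	.	.	T	Y	C	A	.
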