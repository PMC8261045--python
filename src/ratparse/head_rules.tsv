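# Collins-style head-percolation table: category <TAB> direction <TAB> priority list
# direction: the scan order over children when searching each priority label.
# Unknown categories fall back to the rightmost child.
S	left	VP S SBAR ADJP UCP NP
SBAR	left	S SQ SINV SBAR FRAG IN DT WHNP WHPP WHADVP WHADJP
SBARQ	left	SQ S SINV SBARQ FRAG
SINV	left	VBZ VBD VBP VB MD VP S SINV ADJP NP
SQ	left	VBZ VBD VBP VB MD VP SQ
VP	left	VBD VBN MD VBZ VB VBG VBP VP ADJP NN NNS NP TO
NP	right	NN NNS NNP NNPS NX POS JJR CD JJ JJS RB QP NP PRP
WHNP	left	WP WDT WP$ WHADJP WHPP WHNP NN
WHPP	left	IN TO FW
WHADVP	right	CC WRB
PP	left	IN TO VBG VBN RP FW
ADJP	right	NNS QP NN $ ADVP JJ VBN VBG ADJP JJR NP JJS DT FW RBR RBS SBAR RB
ADVP	right	RB RBR RBS FW ADVP TO CD JJR JJ IN NP JJS NN
QP	left	$ IN NNS NN JJ RB DT CD NCD QP JJR JJS
PRT	right	RP
FRAG	right	NN NP VP S
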