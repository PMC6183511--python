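file_type	version	block	label	required
O	1	A	SOD version	yes
O	1	A	File type	yes
O	1	A	Fossil group	yes
O	1	A	Observer	yes
O	1	A	Date	no
O	1	A	Leg	no
O	1	A	Site	yes
O	1	A	Hole	yes
O	1	A	Latitude	no
O	1	A	Longitude	no
O	1	A	Ocean	no
O	1	B	Sample	yes
O	1	B	Core	yes
O	1	B	Section	yes
O	1	B	Interval (cm)	yes
O	1	B	Depth (mbsf)	no
O	1	B	Zone	no
O	1	B	Age	no
O	1	B	Tracks (full)	no
O	1	B	Tracks (rare)	no
O	1	B	Exclusion threshold (%)	no
O	1	C	Genus	yes
O	1	C	Species	yes
O	1	C	Author	no
O	1	C	Excluded	no
L	1	A	SOD version	yes
L	1	A	File type	yes
L	1	A	Fossil group	yes
L	1	A	Observer	yes
L	1	A	Date	no
L	1	A	Region	yes
L	1	A	Section	yes
L	1	A	Latitude	no
L	1	A	Longitude	no
L	1	A	Formation	no
L	1	A	Lithology	no
L	1	B	Sample	yes
L	1	B	Level	yes
L	1	B	Zone	no
L	1	B	Age	no
L	1	B	Tracks (full)	no
L	1	B	Tracks (rare)	no
L	1	B	Exclusion threshold (%)	no
L	1	C	Genus	yes
L	1	C	Species	yes
L	1	C	Author	no
L	1	C	Excluded	no
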