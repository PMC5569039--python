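# Transcribed target-gene table: polysaccharide-metabolism genes with W-box
# counts and hit positions (ATG-relative offsets) in 1-kb upstream regions.
# Rows transcribed verbatim, including the repeated glucan-glucosidase trio.
# columns: function, protein_class, annotation_id, wbox_count, positions (comma-joined)
function	protein_class	annotation_id	wbox_count	positions
Polysaccharide biosynthesis	Glucosyltransferase	Dendrobium_GLEAN_10093863	3	-106,-33,-127
Polysaccharide biosynthesis	Glucosyltransferase	Dendrobium_GLEAN_10093854	3	-260,-312,-168
Polysaccharide biosynthesis	Glucosyltransferase	Dendrobium_GLEAN_10034225	3	-905,-49,-110
Polysaccharide biosynthesis	Glucosyltransferase	Dendrobium_GLEAN_10037085	3	-700,-498,-366
Polysaccharide biosynthesis	Glucosyltransferase	Dendrobium_GLEAN_10004757	3	-767,-95,-946
Polysaccharide biosynthesis	Glucosyltransferase	Dendrobium_GLEAN_10114838	3	-449,-46,-580
Polysaccharide biosynthesis	Glucosyltransferase	Dendrobium_GLEAN_10101470	3	-304,-741,-416
Polysaccharide biosynthesis	Xylosyltransferase	Dendrobium_GLEAN_10043111	4	-455,-843,-793,-725
Polysaccharide biosynthesis	Xylosyltransferase	Dendrobium_GLEAN_10090448	3	-132,-57,-85
Polysaccharide biosynthesis	Galactosyltransferase	Dendrobium_GLEAN_10089526	3	-123,-730,-961
Polysaccharide biosynthesis	Galactosyltransferase	Dendrobium_GLEAN_10090448	3	-132,-57,-85
Polysaccharide biosynthesis	Galactosyltransferase	Dendrobium_GLEAN_10011963	5	-621,-825,-106,-663,-11
Polysaccharide biosynthesis	Galactosyltransferase	Dendrobium_GLEAN_10125164	3	-628,-597,-585
Polysaccharide biosynthesis	Galactosyltransferase	Dendrobium_GLEAN_10117276	5	-928,-582,-220,-158,-304
Polysaccharide biosynthesis	Cellulose synthase	Dendrobium_GLEAN_10105279	3	-666,-910,-132
Polysaccharide biosynthesis	Cellulose synthase	Dendrobium_GLEAN_10115475	3	-79,-307,-234
Polysaccharide biosynthesis	Cellulose synthase	Dendrobium_GLEAN_10037286	3	-366,-531,-157
Polysaccharide biosynthesis	Cellulose synthase	Dendrobium_GLEAN_10023561	3	-156,-931,-534
Polysaccharide biosynthesis	Cellulose synthase	Dendrobium_GLEAN_10061727	3	-280,-596,-242
Polysaccharide biosynthesis	Cellulose synthase	Dendrobium_GLEAN_10064843	7	-577,-516,-628,-536,-857,-527,-127
Polysaccharide biosynthesis	Mannan synthase	Dendrobium_GLEAN_10127097	3	-848,-286,-991
Polysaccharide biosynthesis	Sugar transporter	Dendrobium_GLEAN_10110460	3	-485,-145,-95
Polysaccharide biosynthesis	Sugar transporter	Dendrobium_GLEAN_10127692	3	-425,-100,-420
Polysaccharide hydrolysis	Mannan mannosidase	Dendrobium_GLEAN_10059324	4	-136,-391,-784,-369
Polysaccharide hydrolysis	Mannan mannosidase	Dendrobium_GLEAN_10032958	12	-920,-620,-602,-267,-667,-584,-679,-809,-359,-405,-592,-508
Polysaccharide hydrolysis	Glucan glucosidase	Dendrobium_GLEAN_10014101	9	-763,-915,-501,-475,-604,-814,-788,-730,-567
Polysaccharide hydrolysis	Glucan glucosidase	Dendrobium_GLEAN_10108908	3	-271,-536,-41
Polysaccharide hydrolysis	Glucan glucosidase	Dendrobium_GLEAN_10076876	3	-471,-580,-9
Polysaccharide hydrolysis	Glucan glucosidase	Dendrobium_GLEAN_10014101	9	-763,-915,-501,-475,-604,-814,-788,-730,-567
Polysaccharide hydrolysis	Glucan glucosidase	Dendrobium_GLEAN_10108908	3	-271,-536,-41
Polysaccharide hydrolysis	Glucan glucosidase	Dendrobium_GLEAN_10076876	3	-471,-580,-9
Polysaccharide hydrolysis	Xyloglucan hydrolase	Dendrobium_GLEAN_10031220	4	-28,-187,-344,-419
Polysaccharide hydrolysis	Xyloglucan hydrolase	Dendrobium_GLEAN_10116796	3	-171,-467,-857
Polysaccharide hydrolysis	Xyloglucan hydrolase	Dendrobium_GLEAN_10095975	3	-299,-32,-95
Polysaccharide hydrolysis	Xyloglucan hydrolase	Dendrobium_GLEAN_10059366	4	-883,-778,-808,-686
Polysaccharide hydrolysis	Amylase	Dendrobium_GLEAN_10097224	3	-146,-937,-909
Polysaccharide hydrolysis	Amylase	Dendrobium_GLEAN_10053987	4	-781,-251,-961,-177
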