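# Affect lexicon: word  polarity[-1,1]  subjectivity[0,1]
# Lines starting with '#' are comments; columns are whitespace-separated.
# Weights are hand-assigned on conventional sentiment-lexicon conventions:
# strong affect words carry high subjectivity; hedges and appraisal verbs
# carry moderate subjectivity with near-zero polarity.
abysmal -0.95 0.95
admirable 0.75 0.85
admiration 0.7 0.8
adore 0.85 0.95
afraid -0.6 0.8
aggressive -0.45 0.7
agitated -0.55 0.8
agony -0.9 0.95
alive 0.5 0.6
amazed 0.75 0.9
amazing 0.85 0.9
amused 0.55 0.8
anger -0.75 0.9
angry -0.75 0.9
anguish -0.85 0.95
annoyed -0.5 0.8
anxious -0.55 0.85
apathetic -0.35 0.7
appealing 0.55 0.7
appreciate 0.6 0.7
apprehensive -0.45 0.75
ashamed -0.6 0.85
astonishing 0.7 0.85
attractive 0.6 0.75
awe 0.65 0.85
awful -0.85 0.9
awkward -0.4 0.7
bad -0.65 0.75
balanced 0.35 0.45
beautiful 0.8 0.85
beauty 0.7 0.75
bitter -0.6 0.8
bland -0.35 0.6
bleak -0.6 0.75
bliss 0.9 0.95
blissful 0.9 0.95
bold 0.4 0.6
boring -0.55 0.8
bothered -0.45 0.75
brilliant 0.85 0.9
bright 0.5 0.55
broken -0.6 0.7
calm 0.55 0.65
calming 0.6 0.7
captivating 0.75 0.85
carefree 0.55 0.7
chaotic -0.45 0.65
charming 0.65 0.8
cheerful 0.75 0.85
cold -0.4 0.55
comfortable 0.55 0.65
comforting 0.6 0.7
compelling 0.55 0.7
confident 0.55 0.7
confused -0.4 0.7
confusing -0.45 0.7
content 0.6 0.7
contempt -0.7 0.85
crushed -0.7 0.85
curious 0.35 0.6
dark -0.45 0.55
dazzling 0.75 0.85
dead -0.65 0.6
delicate 0.35 0.5
delight 0.8 0.9
delightful 0.8 0.9
depressed -0.8 0.9
depressing -0.75 0.85
despair -0.9 0.95
desperate -0.7 0.85
devastated -0.9 0.95
disappointed -0.6 0.8
disappointing -0.6 0.8
disgust -0.8 0.9
disgusting -0.85 0.9
dismal -0.7 0.8
distressed -0.65 0.85
disturbing -0.65 0.8
drab -0.4 0.65
dramatic 0.25 0.6
dreadful -0.85 0.9
dreamy 0.55 0.75
dull -0.5 0.7
dynamic 0.4 0.55
ecstatic 0.95 0.95
eerie -0.4 0.65
elated 0.85 0.9
elegant 0.65 0.75
embarrassed -0.5 0.8
empty -0.55 0.65
enchanting 0.75 0.85
energetic 0.55 0.65
engaging 0.55 0.7
enjoy 0.65 0.75
enjoyable 0.65 0.75
enraged -0.85 0.95
enthusiastic 0.7 0.8
envious -0.5 0.8
euphoric 0.95 0.95
evocative 0.45 0.65
exciting 0.7 0.8
excellent 0.85 0.85
exhausted -0.55 0.7
exhilarating 0.8 0.9
expressive 0.45 0.6
exquisite 0.8 0.85
fabulous 0.8 0.9
fantastic 0.85 0.9
fascinating 0.7 0.8
fear -0.7 0.85
fearful -0.65 0.85
fierce -0.3 0.6
fine 0.3 0.4
flat -0.3 0.5
fond 0.55 0.7
forlorn -0.65 0.8
fragile -0.3 0.5
frantic -0.5 0.75
fresh 0.45 0.55
frightened -0.65 0.85
frightening -0.7 0.85
frustrated -0.6 0.85
frustrating -0.6 0.8
fun 0.65 0.75
furious -0.85 0.95
gentle 0.5 0.6
glad 0.6 0.75
gloomy -0.6 0.75
glorious 0.8 0.85
good 0.6 0.65
gorgeous 0.8 0.85
graceful 0.6 0.7
grand 0.55 0.6
grateful 0.7 0.8
great 0.7 0.7
grief -0.85 0.9
grim -0.65 0.75
gripping 0.5 0.7
gross -0.7 0.85
happy 0.8 0.85
harmonious 0.6 0.65
harsh -0.55 0.7
hate -0.9 0.95
hateful -0.85 0.95
haunting -0.35 0.7
heartbreaking -0.75 0.9
heartwarming 0.75 0.9
heavy -0.3 0.45
hideous -0.85 0.9
hopeful 0.6 0.75
hopeless -0.8 0.9
horrible -0.85 0.9
horrific -0.9 0.95
horror -0.85 0.9
hostile -0.7 0.85
humble 0.35 0.55
hurt -0.6 0.75
hypnotic 0.4 0.65
imaginative 0.55 0.65
immersive 0.5 0.65
impressive 0.65 0.7
inspired 0.65 0.8
inspiring 0.7 0.8
intense 0.2 0.6
interesting 0.5 0.65
intimate 0.45 0.65
intriguing 0.55 0.7
irritated -0.55 0.8
irritating -0.55 0.8
joy 0.85 0.9
joyful 0.85 0.9
jubilant 0.85 0.9
keen 0.4 0.55
kind 0.55 0.65
lively 0.6 0.7
lonely -0.6 0.8
lost -0.45 0.6
lovable 0.7 0.85
love 0.85 0.9
lovely 0.75 0.85
luminous 0.55 0.6
lyrical 0.45 0.6
mad -0.65 0.85
magical 0.7 0.8
magnificent 0.85 0.85
majestic 0.7 0.75
marvelous 0.8 0.9
meaningful 0.5 0.6
melancholic -0.5 0.75
melancholy -0.5 0.75
memorable 0.55 0.65
menacing -0.6 0.75
merry 0.7 0.8
mesmerizing 0.75 0.85
miserable -0.8 0.9
miss -0.35 0.6
morbid -0.6 0.75
mournful -0.65 0.8
moving 0.55 0.7
mysterious 0.25 0.55
nasty -0.7 0.85
nice 0.55 0.65
nightmare -0.8 0.9
nostalgic 0.3 0.7
numb -0.45 0.65
offensive -0.65 0.85
ominous -0.55 0.7
optimistic 0.6 0.75
outraged -0.8 0.95
outstanding 0.8 0.85
overwhelmed -0.35 0.75
overwhelming -0.3 0.7
painful -0.7 0.8
panic -0.7 0.9
passionate 0.6 0.8
pathetic -0.7 0.9
peaceful 0.65 0.7
perfect 0.9 0.9
pessimistic -0.55 0.8
placid 0.4 0.55
playful 0.55 0.7
pleasant 0.6 0.7
pleased 0.6 0.75
pleasing 0.6 0.7
poetic 0.5 0.65
poignant 0.35 0.7
positive 0.55 0.6
powerful 0.45 0.55
pretty 0.6 0.7
proud 0.6 0.75
pure 0.45 0.5
radiant 0.7 0.75
raw 0.05 0.5
refreshing 0.6 0.7
regret -0.55 0.8
relaxed 0.55 0.65
relaxing 0.55 0.65
relieved 0.55 0.75
remarkable 0.65 0.7
repulsive -0.85 0.9
resentful -0.65 0.85
restless -0.45 0.7
revolting -0.85 0.9
rich 0.45 0.5
romantic 0.55 0.75
rough -0.35 0.5
sad -0.7 0.85
sadness -0.7 0.85
satisfying 0.6 0.7
scared -0.65 0.85
scary -0.6 0.8
serene 0.65 0.7
serious -0.1 0.4
shocked -0.4 0.8
shocking -0.45 0.8
sick -0.6 0.7
silly -0.2 0.7
sincere 0.5 0.6
sinister -0.7 0.8
solemn -0.2 0.5
somber -0.45 0.65
soothing 0.6 0.7
sorrow -0.8 0.9
sorrowful -0.75 0.9
spectacular 0.8 0.85
splendid 0.8 0.85
startling -0.25 0.7
still 0.1 0.3
stimulating 0.55 0.65
strange -0.2 0.55
stressed -0.6 0.8
striking 0.5 0.65
strong 0.4 0.5
stunning 0.8 0.85
stunned -0.2 0.75
sublime 0.8 0.85
subtle 0.3 0.5
suffering -0.8 0.9
superb 0.85 0.85
surprised 0.25 0.75
surprising 0.25 0.7
suspenseful 0.15 0.6
sweet 0.6 0.7
tedious -0.5 0.75
tender 0.55 0.7
tense -0.45 0.7
terrible -0.85 0.9
terrific 0.8 0.85
terrified -0.85 0.95
terrifying -0.8 0.9
thoughtful 0.45 0.6
thrilled 0.8 0.9
thrilling 0.75 0.85
tired -0.45 0.65
torment -0.85 0.9
tragic -0.75 0.85
tranquil 0.6 0.65
troubled -0.55 0.75
turbulent -0.45 0.65
ugly -0.7 0.8
uncomfortable -0.5 0.75
uneasy -0.45 0.75
unhappy -0.7 0.85
unpleasant -0.6 0.75
unsettling -0.5 0.75
upbeat 0.6 0.7
upset -0.6 0.85
upsetting -0.6 0.8
vibrant 0.65 0.7
vivid 0.55 0.6
warm 0.55 0.6
weary -0.5 0.7
weird -0.3 0.65
wonder 0.6 0.7
wonderful 0.85 0.9
worried -0.55 0.8
worry -0.55 0.8
worst -0.95 0.9
worthless -0.8 0.9
wretched -0.85 0.9
zest 0.6 0.7
# Appraisal / hedging terms: near-neutral polarity, nonzero subjectivity.
# These decouple subjectivity targets from polarity targets.
apparently 0.0 0.5
arguably 0.0 0.6
assume 0.0 0.45
believe 0.0 0.6
consider 0.0 0.4
doubt -0.1 0.6
feel 0.0 0.65
feeling 0.0 0.6
guess 0.0 0.55
imagine 0.05 0.55
impression 0.0 0.5
maybe 0.0 0.5
opinion 0.0 0.7
perhaps 0.0 0.5
personally 0.0 0.8
possibly 0.0 0.5
presumably 0.0 0.55
probably 0.0 0.5
reckon 0.0 0.6
seem 0.0 0.45
seemingly 0.0 0.5
seems 0.0 0.45
sense 0.0 0.4
somewhat 0.0 0.4
suppose 0.0 0.5
think 0.0 0.55
thought 0.0 0.45
view 0.0 0.35
wondering 0.05 0.55
# Low-subjectivity descriptive terms: mild polarity, largely factual tone.
abstract 0.0 0.25
accurate 0.2 0.2
ancient 0.05 0.15
classical 0.1 0.2
colorful 0.3 0.3
complex 0.0 0.3
detailed 0.2 0.25
geometric 0.0 0.1
historical 0.05 0.1
large 0.0 0.1
layered 0.05 0.2
modern 0.1 0.2
monochrome 0.0 0.15
ornate 0.15 0.3
realistic 0.15 0.25
small 0.0 0.1
symmetrical 0.05 0.15
textured 0.05 0.2
traditional 0.05 0.2
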